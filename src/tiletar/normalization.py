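"""Array normalization and replicate summarization.

Two-color tiling arrays are made comparable in two steps, in this order:
(1) each column is shifted additively on the log2 scale so that its
random-probe mean equals the grand random-probe mean, then (2) all columns
(both conditions jointly) are quantile-normalized.  Replicates are then
summarized per probe and condition by the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation_io import ProbeDesign

log = logging.getLogger(__name__)

CONDITIONS = ("unfertilized", "fertilized")
DYES = ("cy3", "cy5")


@dataclass(frozen=True)
class SampleInfo:
    """One array channel: its true biological condition, replicate and dye.

    ``swapped`` marks the dye-swap hybridization (the condition↔dye pairing
    reversed relative to the other replicates).  ``condition`` is always the
    true condition, so downstream code never needs to re-resolve the swap.
    """

    condition: str
    replicate: int
    dye: str
    swapped: bool = False

    @property
    def name(self) -> str:
        base = f"{self.condition}.{self.replicate}.{self.dye}"
        return base + ".swap" if self.swapped else base

    @classmethod
    def parse(cls, name: str) -> "SampleInfo":
        parts = name.split(".")
        if len(parts) not in (3, 4) or (len(parts) == 4 and parts[3] != "swap"):
            raise ValueError(f"bad sample column name {name!r}")
        return cls(parts[0], int(parts[1]), parts[2], len(parts) == 4)


@dataclass
class IntensityMatrix:
    """probe × sample log2 fluorescence values with sample metadata."""

    data: pd.DataFrame
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if list(self.data.columns) != names:
            raise ValueError("sample metadata does not match matrix columns")
        if self.data.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        for cond in {s.condition for s in self.samples}:
            n = sum(s.condition == cond for s in self.samples)
            if n < 2:
                log.warning("condition %s has only %d column(s)", cond, n)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def columns_for(self, condition: str) -> list[str]:
        return [s.name for s in self.samples if s.condition == condition]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), list(self.samples))


def read_intensity_matrix(path: str | Path) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    df.index.name = "probe_id"
    samples = [SampleInfo.parse(c) for c in df.columns]
    return IntensityMatrix(df.astype(float), samples)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def scale_to_random_mean(matrix: IntensityMatrix, design: ProbeDesign) -> IntensityMatrix:
    """Shift each column so its random-probe mean equals the grand mean.

    An additive shift on the log2 scale; experimental and random probes move
    together, so between-array brightness differences are removed without
    touching within-array structure.
    """
    random_ids = [pid for pid in design.random_ids if pid in matrix.data.index]
    if not random_ids:
        raise ValueError(
            "no random probes present in the matrix; background scaling "
            "(and threshold calibration) is impossible"
        )
    sub = matrix.data.loc[random_ids]
    col_means = sub.mean(axis=0)
    grand = float(col_means.mean())
    shifted = matrix.data - (col_means - grand)
    return IntensityMatrix(shifted, list(matrix.samples))


def _quantile_normalize_block(X: np.ndarray) -> np.ndarray:
    n, m = X.shape
    if m < 2:
        return X.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(n, dtype=float)
    for j in range(m):
        ranks = rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, ref)
    return out


def quantile_normalize(
    matrix: IntensityMatrix, within_condition: bool = False
) -> IntensityMatrix:
    """Force every column onto the mean-of-sorted-columns reference distribution.

    Rank order within each column is preserved; ties receive the mean of the
    reference values at their tied ranks (average-rank convention).
    Idempotent to numerical tolerance.

    By default all columns are normalized jointly (both conditions share one
    reference distribution).  ``within_condition=True`` normalizes each
    condition's columns separately, which preserves genuine global
    differences between conditions at the cost of leaving the conditions'
    marginal distributions unequal.
    """
    if within_condition:
        out = matrix.data.to_numpy(dtype=float).copy()
        cols = list(matrix.data.columns)
        for cond in sorted({s.condition for s in matrix.samples}):
            idx = [cols.index(name) for name in matrix.columns_for(cond)]
            out[:, idx] = _quantile_normalize_block(out[:, idx])
    else:
        out = _quantile_normalize_block(matrix.data.to_numpy(dtype=float))
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return IntensityMatrix(df, list(matrix.samples))


def normalize(
    matrix: IntensityMatrix, design: ProbeDesign, within_condition: bool = False
) -> IntensityMatrix:
    """Full normalization: random-probe mean scaling, then quantile normalization."""
    return quantile_normalize(scale_to_random_mean(matrix, design), within_condition)


def summarize_replicates(matrix: IntensityMatrix) -> pd.DataFrame:
    """Median across replicate columns per (probe, condition).

    Returns a probe × condition DataFrame.  Dye-swap columns already carry
    their true condition, so no further resolution is needed here.
    """
    conditions = sorted({s.condition for s in matrix.samples})
    out = {}
    for cond in conditions:
        cols = matrix.columns_for(cond)
        if not cols:
            raise ValueError(f"condition {cond} has no columns")
        out[cond] = matrix.data[cols].median(axis=1)
    return pd.DataFrame(out, index=matrix.data.index)
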