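"""Empirical-null thresholding and gene expression calling.

A detection threshold is the (1 − FPR) quantile of the random-probe signal
(default FPR 0.01, i.e. the 99th percentile), so in expectation only ~1% of
null probes exceed it.  A probe is positive if its summarized value is
strictly greater than the threshold.  A gene is testable when at least one
probe overlaps its exons, and called expressed when strictly more than 80%
of its tiled length is covered by positive probes.  The gene expression
score is the median probe signal over background, where background is the
post-normalization random-probe mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import (
    Gene,
    GenomeAnnotation,
    Interval,
    ProbeDesign,
    merge_intervals,
    union_length,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Threshold:
    """Empirical false-positive-rate detection threshold."""

    value: float
    fpr: float
    n_random: int


def fpr_threshold(random_values, fpr: float = 0.01) -> Threshold:
    """Empirical (1 − fpr) quantile of the random-probe values.

    Uses the linear-interpolation quantile definition, pinned for
    reproducibility.  Warns below 1000 values (quantile tail unstable).
    """
    arr = np.asarray(random_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no random-probe values; cannot calibrate a threshold")
    if not (0.0 < fpr < 1.0):
        raise ValueError(f"fpr must be in (0, 1), got {fpr}")
    if arr.size < 1000:
        log.warning("only %d random values; the %.4g quantile is unstable", arr.size, 1 - fpr)
    value = float(np.quantile(arr, 1.0 - fpr))
    return Threshold(value=value, fpr=fpr, n_random=int(arr.size))


def call_positive(values: pd.Series, threshold: Threshold) -> pd.Series:
    """Positive iff strictly greater than the threshold value."""
    return values > threshold.value


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    testable: bool
    expressed: bool
    score: float  # NaN when untestable
    tiled_length: int
    expressed_tiled_length: int


@dataclass
class ExpressionCallSet:
    """Per-gene testability, expression calls and scores for one condition."""

    condition: str
    table: pd.DataFrame  # index gene_id; testable, expressed, score, tiled_length, expressed_tiled_length

    def __post_init__(self) -> None:
        bad = self.table["expressed"] & ~self.table["testable"]
        if bad.any():
            raise ValueError("expressed genes must be testable")

    @property
    def expressed_ids(self) -> set[str]:
        return set(self.table.index[self.table["expressed"]])

    @property
    def testable_ids(self) -> set[str]:
        return set(self.table.index[self.table["testable"]])


def _exon_probe_overlaps(gene: Gene, design: ProbeDesign) -> dict[str, list[tuple[int, int]]]:
    """Per probe, the clipped (probe ∩ exon) pieces for this gene."""
    pieces: dict[str, list[tuple[int, int]]] = {}
    for s, e in gene.exons:
        for p in design.probes_overlapping(Interval(gene.chromosome, s, e)):
            a = p.address
            assert a is not None
            pieces.setdefault(p.probe_id, []).append((max(s, a.start), min(e, a.end)))
    return pieces


def tiled_length(gene: Gene, design: ProbeDesign) -> int:
    """Length of the union of (probe ∩ exon union) over all experimental probes."""
    pieces = _exon_probe_overlaps(gene, design)
    return union_length(p for plist in pieces.values() for p in plist)


def call_gene(
    gene: Gene,
    positives: pd.Series,
    design: ProbeDesign,
    values: pd.Series | None = None,
    baseline: float = 0.0,
    frac: float = 0.8,
) -> GeneCall:
    """Call one gene from per-probe positives.

    ``testable`` iff the gene has tiled length > 0; ``expressed`` iff the
    positive-probe coverage of its exon union exceeds ``frac`` of the tiled
    length (strict inequality).  ``score`` is the median of (value −
    baseline) over probes overlapping exons when ``values`` are given.
    """
    pieces = _exon_probe_overlaps(gene, design)
    all_pieces = [piece for plist in pieces.values() for piece in plist]
    tiled = union_length(all_pieces)
    if tiled == 0:
        return GeneCall(gene.gene_id, False, False, float("nan"), 0, 0)
    pos_pieces = [
        piece
        for pid, plist in pieces.items()
        if pid in positives.index and bool(positives[pid])
        for piece in plist
    ]
    expressed_len = union_length(pos_pieces)
    expressed = expressed_len / tiled > frac
    score = float("nan")
    if values is not None:
        overlapping = [pid for pid in pieces if pid in values.index]
        if overlapping:
            score = float(np.median(values[overlapping].to_numpy()) - baseline)
    return GeneCall(gene.gene_id, True, expressed, score, tiled, expressed_len)


def call_genes(
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    summary: pd.DataFrame,
    thresholds: dict[str, Threshold],
    baselines: dict[str, float],
    frac: float = 0.8,
) -> dict[str, ExpressionCallSet]:
    """Call every gene in every condition of a summarized matrix.

    ``summary`` is the probe × condition median table from
    :func:`tiletar.normalization.summarize_replicates`.
    """
    callsets: dict[str, ExpressionCallSet] = {}
    for cond in summary.columns:
        values = summary[cond]
        positives = call_positive(values, thresholds[cond])
        rows = []
        for gene in annotation.genes:
            c = call_gene(gene, positives, design, values, baselines.get(cond, 0.0), frac)
            rows.append(
                (c.gene_id, c.testable, c.expressed, c.score, c.tiled_length,
                 c.expressed_tiled_length)
            )
        table = pd.DataFrame(
            rows,
            columns=["gene_id", "testable", "expressed", "score", "tiled_length",
                     "expressed_tiled_length"],
        ).set_index("gene_id")
        callsets[cond] = ExpressionCallSet(cond, table)
    return callsets


def random_probe_baseline(summary: pd.DataFrame, design: ProbeDesign) -> dict[str, float]:
    """Post-normalization random-probe mean per condition (the background level)."""
    ids = [pid for pid in design.random_ids if pid in summary.index]
    if not ids:
        raise ValueError("no random probes in summary")
    return {cond: float(summary.loc[ids, cond].mean()) for cond in summary.columns}


def condition_thresholds(
    summary: pd.DataFrame, design: ProbeDesign, fpr: float = 0.01, pooled: bool = False
) -> dict[str, Threshold]:
    """FPR thresholds per condition (default) or one pooled threshold."""
    ids = [pid for pid in design.random_ids if pid in summary.index]
    if not ids:
        raise ValueError("no random probes in summary")
    if pooled:
        t = fpr_threshold(summary.loc[ids].to_numpy().ravel(), fpr)
        return {cond: t for cond in summary.columns}
    return {cond: fpr_threshold(summary.loc[ids, cond], fpr) for cond in summary.columns}


def expression_summary(callset: ExpressionCallSet, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-chromosome testable/expressed counts and fractions, plus totals."""
    chrom_of = {g.gene_id: g.chromosome for g in annotation.genes}
    t = callset.table.copy()
    t["chromosome"] = [chrom_of[g] for g in t.index]
    rows = []
    for c in annotation.chromosomes:
        sub = t[t["chromosome"] == c.name]
        n_testable = int(sub["testable"].sum())
        n_expressed = int(sub["expressed"].sum())
        rows.append(
            (c.name, c.chrom_class, len(sub), n_testable, n_expressed,
             n_expressed / n_testable if n_testable else float("nan"))
        )
    n_testable = int(t["testable"].sum())
    n_expressed = int(t["expressed"].sum())
    rows.append(
        ("TOTAL", "", len(t), n_testable, n_expressed,
         n_expressed / n_testable if n_testable else float("nan"))
    )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "class", "n_genes", "n_testable", "n_expressed", "fraction"],
    )
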