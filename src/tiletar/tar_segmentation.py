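"""Transcriptionally active region (TAR) segmentation and filtering.

Positive probes are joined into a TAR when they are adjacent in the tiled
design with no intermittent non-positive probe (maxgap = 0: successive probe
intervals overlapping or abutting), the run spans at least ``minrun`` bp from
the midpoint of its first positive probe to the midpoint of its last
(minrun = 45, which with ~54 bp probes overlapping ~12 bp implies at least 3
adjacent positive probes), and the run has at least ``min_probes`` probes.
A physical tiling gap breaks a run even between design-consecutive probes,
because bridging it would assert expression over untiled sequence.

Novel TARs are those strictly longer than 100 bp lying strictly more than
100 bp from every annotated gene span (introns included) on the assembly.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation, Interval, ProbeDesign, gene_span


@dataclass(frozen=True)
class TAR:
    """A contiguous transcriptionally active genomic interval."""

    id: str
    condition: str
    interval: Interval
    n_probes: int
    midpoint_span: float  # midpoint of first positive probe to midpoint of last
    mean_signal: float  # mean log2 over background; NaN when values not supplied


def segment_tars(
    positives: pd.Series,
    design: ProbeDesign,
    values: pd.Series | None = None,
    baseline: float = 0.0,
    condition: str = "",
    minrun: float = 45,
    maxgap: int = 0,
    min_probes: int = 3,
) -> list[TAR]:
    """Join positive probes into TARs by the run rules above.

    ``positives`` is a boolean Series indexed by probe id (only experimental
    probes are consulted).  The reported TAR extent runs from the first
    probe's start to the last probe's end; the ``minrun`` test uses the
    midpoint span.  TARs are emitted in genomic order with deterministic ids.
    """
    tars: list[TAR] = []
    run: list = []

    def flush() -> None:
        if len(run) >= min_probes:
            first, last = run[0].address, run[-1].address
            span = last.midpoint - first.midpoint
            if span >= minrun:
                iv = Interval(first.chromosome, first.start, last.end)
                signal = float("nan")
                if values is not None:
                    ids = [p.probe_id for p in run if p.probe_id in values.index]
                    if ids:
                        signal = float(values[ids].mean() - baseline)
                tars.append(
                    TAR(
                        id=f"TAR.{condition or 'na'}.{len(tars) + 1:05d}",
                        condition=condition,
                        interval=iv,
                        n_probes=len(run),
                        midpoint_span=span,
                        mean_signal=signal,
                    )
                )
        run.clear()

    for p in design.experimental:
        a = p.address
        is_pos = bool(positives.get(p.probe_id, False))
        if run:
            pa = run[-1].address
            contiguous = (
                a.chromosome == pa.chromosome and a.start - pa.end <= maxgap
            )
            if not (is_pos and contiguous):
                flush()
        if is_pos:
            run.append(p)
    flush()
    return tars


def filter_novel(
    tars: list[TAR],
    annotation: GenomeAnnotation,
    min_len: int = 100,
    min_dist: int = 100,
) -> list[TAR]:
    """Keep TARs strictly longer than ``min_len`` and strictly more than
    ``min_dist`` bp from every gene span on their chromosome."""
    spans = annotation.gene_spans_by_chromosome()
    # per chromosome: starts sorted for bisection; running max of ends
    index: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, lst in spans.items():
        starts = [iv.start for iv in lst]
        ends = [iv.end for iv in lst]
        run_max: list[int] = []
        m = 0
        for e in ends:
            m = max(m, e)
            run_max.append(m)
        index[chrom] = (starts, run_max)

    kept: list[TAR] = []
    for tar in tars:
        iv = tar.interval
        if iv.length <= min_len:
            continue
        starts, run_max = index.get(iv.chromosome, ([], []))
        # nearest gene to the right: smallest start ≥ tar end
        dist_right = math.inf
        i = bisect.bisect_left(starts, iv.end)
        if i < len(starts):
            dist_right = starts[i] - iv.end
        # nearest gene end to the left among genes starting before tar end
        dist_left = math.inf
        if i > 0:
            left_end = run_max[i - 1]
            dist_left = iv.start - left_end  # ≤ 0 means overlap/abut
        nearest = min(dist_left, dist_right)
        if nearest > min_dist:
            kept.append(tar)
    return kept


def unique_tars(a: list[TAR], b: list[TAR]) -> list[TAR]:
    """Members of ``a`` with zero bp overlap with every member of ``b``."""
    by_chrom: dict[str, list[TAR]] = {}
    for t in b:
        by_chrom.setdefault(t.interval.chromosome, []).append(t)
    out = []
    for t in a:
        others = by_chrom.get(t.interval.chromosome, [])
        if not any(t.interval.overlaps(o.interval) for o in others):
            out.append(t)
    return out


def estimate_novel_genes(n_tars: int, exons_per_gene: float = 4.4) -> int:
    """Novel-gene count implied by a TAR count: floor(n_tars / exons_per_gene).

    TARs are candidate novel exons, so dividing by the genome's average
    exons-per-gene gives a conservative gene-count estimate.
    """
    if n_tars < 0:
        raise ValueError("n_tars must be non-negative")
    if exons_per_gene <= 0:
        raise ValueError("exons_per_gene must be positive")
    q = n_tars / exons_per_gene
    f = math.floor(q)
    # snap up when floating division lands a hair below an exact integer ratio
    if (f + 1) - q < 1e-9:
        f += 1
    return f


def tar_size_distribution(tars: list[TAR], bin_edges) -> pd.DataFrame:
    """Histogram of TAR lengths over the given bin edges (counts + fractions)."""
    lengths = np.array([t.interval.length for t in tars], dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if lengths.size and (lengths.min() < edges[0] or lengths.max() > edges[-1]):
        raise ValueError("bin edges do not cover the observed TAR length range")
    counts, _ = np.histogram(lengths, bins=edges)
    total = counts.sum()
    fractions = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
         "fraction": fractions}
    )


def tar_chromosome_counts(tars: list[TAR], annotation: GenomeAnnotation) -> pd.DataFrame:
    """TAR count and chromosome length per chromosome (feeds the length correlation)."""
    counts = {c.name: 0 for c in annotation.chromosomes}
    for t in tars:
        if t.interval.chromosome in counts:
            counts[t.interval.chromosome] += 1
    return pd.DataFrame(
        {
            "chromosome": [c.name for c in annotation.chromosomes],
            "n_tars": [counts[c.name] for c in annotation.chromosomes],
            "length": [c.length for c in annotation.chromosomes],
        }
    )


def match_planted(
    detected: list[TAR], planted: list[Interval]
) -> tuple[float, float]:
    """(precision, recall) of detected TARs against planted truth intervals.

    A detected TAR matches when it overlaps a planted interval by ≥1 bp.
    """
    if not detected and not planted:
        return float("nan"), float("nan")
    matched_d = sum(
        1 for t in detected if any(t.interval.overlaps(p) for p in planted)
    )
    matched_p = sum(
        1 for p in planted if any(t.interval.overlaps(p) for t in detected)
    )
    precision = matched_d / len(detected) if detected else float("nan")
    recall = matched_p / len(planted) if planted else float("nan")
    return precision, recall
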