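"""Enrichment and comparison statistics, and ortholog group classification.

The enrichment question throughout is: does a gene list (female-biased
genes, male-linked genes, ...) contain maternally expressed genes more often
than the genome-wide (or stratum-specific) rate?  The test is the 1-df
Pearson chi-squared goodness of fit of the observed count against a fixed
expected proportion.  Heterogeneity of expressed fractions across
chromosomes uses the G-test (likelihood-ratio chi-squared) on an r × 2
table; TAR size distributions are compared with the two-sample
Kolmogorov–Smirnov statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CHROM_X, GenomeAnnotation
from .expression_calling import ExpressionCallSet

log = logging.getLogger(__name__)

GROUP_A = "A"  # ≥1 ortholog maternally expressed (unfertilized)
GROUP_B = "B"  # ≥1 ortholog expressed in fertilized only
GROUP_C = "C"  # no ortholog expressed in either
GROUP_EXCLUDED = "excluded"  # no testable ortholog on the assembly


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Exact percentage with round-half-up at the requested precision."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoCategoryGof:
    """1-df chi-squared goodness of fit against a fixed expected proportion."""

    observed: int
    n: int
    p_expected: float
    chi2: float
    df: int
    p_value: float


def chisq_gof(observed: int, n: int, p_expected: float) -> TwoCategoryGof:
    """Pearson chi-squared of ``observed`` successes out of ``n`` against
    expected proportion ``p_expected`` (no continuity correction)."""
    if not (0 <= observed <= n):
        raise ValueError("observed must lie in [0, n]")
    if not (0.0 < p_expected < 1.0):
        raise ValueError("p_expected must lie in (0, 1)")
    e1 = n * p_expected
    e2 = n * (1.0 - p_expected)
    if min(e1, e2) < 1:
        log.warning("expected count below 1; the chi-squared approximation is poor")
    chi2 = (observed - e1) ** 2 / e1 + ((n - observed) - e2) ** 2 / e2
    p = float(stats.chi2.sf(chi2, df=1))
    return TwoCategoryGof(observed, n, p_expected, float(chi2), 1, p)


def g_test_heterogeneity(table) -> tuple[float, int, float]:
    """G-test of heterogeneity on an r × 2 count table.

    G = 2 Σ O ln(O/E) with expectations from the row/column marginals;
    df = (r − 1); zero cells contribute 0.  A zero column total makes the
    expectations degenerate and raises an error.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[1] != 2:
        raise ValueError("expected an r × 2 count table")
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    row_tot = O.sum(axis=1)
    col_tot = O.sum(axis=0)
    if np.any(row_tot <= 0):
        raise ValueError("all row totals must be positive")
    if np.any(col_tot <= 0):
        raise ValueError("a zero column total leaves nothing to test")
    E = np.outer(row_tot, col_tot) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = float(2.0 * terms.sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(G, df=df))
    return G, df, p


def ks_two_sample(x, y, bin_edges=None) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: k = sup |ECDF_x − ECDF_y|.

    By default the standard continuous statistic on the raw values with the
    asymptotic p-value.  When ``bin_edges`` are given, the ECDFs are first
    accumulated on those bins (a coarse variant sometimes applied to
    histogrammed size distributions); the p-value then uses the asymptotic
    KS distribution with the effective sample size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_edges is None:
        res = stats.ks_2samp(x, y, method="asymp")
        return float(res.statistic), float(res.pvalue)
    cx = np.histogram(x, bins=bin_edges)[0].cumsum() / x.size
    cy = np.histogram(y, bins=bin_edges)[0].cumsum() / y.size
    k = float(np.max(np.abs(cx - cy)))
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = float(stats.kstwobign.sf(max(0.0, en * k)))
    return k, min(1.0, p)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Ortholog group classification


@dataclass
class OrthologMap:
    """Source-species gene → set of target-species gene ids (possibly empty)."""

    mapping: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.mapping)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV (source_id, target_id); one pair per row.

    A source with an empty target field is recorded with no orthologs.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_skipped and fields[0] in ("source_id", "source_gene_id"):
                header_skipped = True
                continue
            src = fields[0]
            tgt = fields[1] if len(fields) > 1 else ""
            mapping.setdefault(src, set())
            if tgt:
                mapping[src].add(tgt)
    return OrthologMap({k: frozenset(v) for k, v in mapping.items()})


def classify_ortholog_groups(
    omap: OrthologMap,
    unfertilized: ExpressionCallSet,
    fertilized: ExpressionCallSet,
) -> pd.Series:
    """Group each source gene by its orthologs' expression.

    A: ≥1 ortholog expressed in unfertilized eggs (maternally loaded);
    B: none in unfertilized but ≥1 expressed in fertilized eggs;
    C: testable orthologs present but none expressed in either;
    excluded: no ortholog among the testable genes on the assembly.
    Target ids absent from the call sets count as absent from the assembly.
    """
    unf_expr = unfertilized.expressed_ids
    fert_expr = fertilized.expressed_ids
    testable = unfertilized.testable_ids | fertilized.testable_ids
    out = {}
    n_absent = 0
    for src, targets in omap.mapping.items():
        present = {t for t in targets if t in testable}
        n_absent += len(targets) - len(present)
        if not present:
            out[src] = GROUP_EXCLUDED
        elif present & unf_expr:
            out[src] = GROUP_A
        elif present & fert_expr:
            out[src] = GROUP_B
        else:
            out[src] = GROUP_C
    if n_absent:
        log.info("%d ortholog id(s) absent from the tiled assembly", n_absent)
    return pd.Series(out, name="group")


# ---------------------------------------------------------------------------
# Gene-list enrichment


def read_gene_list(path: str | Path) -> list[str]:
    """One-column TSV of gene ids ('#' comments and a 'gene_id' header allowed)."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "gene_id":
                continue
            ids.append(line.split("\t")[0])
    return ids


def _stratum_ids(annotation: GenomeAnnotation, stratum: str) -> set[str]:
    if stratum == "all":
        return {g.gene_id for g in annotation.genes}
    x_names = {c.name for c in annotation.chromosomes if c.chrom_class == CHROM_X}
    if stratum == "X":
        return {g.gene_id for g in annotation.genes if g.chromosome in x_names}
    if stratum == "autosomal":
        return {g.gene_id for g in annotation.genes if g.chromosome not in x_names}
    raise ValueError(f"unknown stratum {stratum!r}")


def enrichment_report(
    callset: ExpressionCallSet,
    gene_lists: dict[str, list[str]],
    annotation: GenomeAnnotation,
    strata: dict[str, str] | None = None,
    expected_precision: int | None = 3,
) -> pd.DataFrame:
    """Maternal-expression enrichment of gene lists against the background rate.

    For each list: members not on the assembly are dropped (counted),
    untestable members are excluded from the denominator, and the expressed
    fraction is tested against the stratum background fraction with
    :func:`chisq_gof`.  ``expected_precision`` rounds the expected proportion
    to that many decimals (as such proportions are usually quoted); ``None``
    uses the exact ratio — the two can differ in the third significant figure.
    """
    strata = strata or {}
    annotated = {g.gene_id for g in annotation.genes}
    rows = []
    for name, ids in gene_lists.items():
        stratum = strata.get(name, "all")
        stratum_ids = _stratum_ids(annotation, stratum)
        background_testable = stratum_ids & callset.testable_ids
        background_expressed = stratum_ids & callset.expressed_ids
        ids_unique = list(dict.fromkeys(ids))
        on_assembly = [i for i in ids_unique if i in annotated]
        n_dropped = len(ids_unique) - len(on_assembly)
        testable = [i for i in on_assembly if i in callset.testable_ids and i in stratum_ids]
        expressed = [i for i in testable if i in callset.expressed_ids]
        if not testable or not background_testable:
            rows.append((name, stratum, len(ids_unique), n_dropped, 0, 0,
                         float("nan"), float("nan"), float("nan"), float("nan")))
            continue
        p_exp = len(background_expressed) / len(background_testable)
        if expected_precision is not None:
            p_exp = round(p_exp, expected_precision)
        gof = chisq_gof(len(expressed), len(testable), p_exp)
        rows.append(
            (name, stratum, len(ids_unique), n_dropped, len(testable), len(expressed),
             len(expressed) / len(testable), p_exp, gof.chi2, gof.p_value)
        )
    return pd.DataFrame(
        rows,
        columns=["list", "stratum", "n_input", "n_dropped", "n_testable",
                 "n_expressed", "fraction", "p_expected", "chi2", "p_value"],
    )
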