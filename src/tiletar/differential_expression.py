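"""Differential expression with an empirical-Bayes moderated t-statistic.

For a balanced two-color dye-swap design the natural unit is the per-replicate
gene-level log2 fold change (fertilized − unfertilized).  Per gene this gives
n replicate ratios; the test is a one-sample moderated t: gene-wise sample
variances s² (d = n − 1 df) are shrunk toward a prior s0² with d0 prior df,

    s̃² = (d0·s0² + d·s²) / (d0 + d),      t̃ = mean / (s̃ / √n),

with t̃ referred to a t distribution on d + d0 df.  The hyperparameters
(d0, s0²) are estimated by the closed-form method of moments on the log
sample variances (the scaled-F / log-moment fit of empirical-Bayes linear
models).  q-values are Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotation_io import GenomeAnnotation, Interval, ProbeDesign
from .normalization import IntensityMatrix

log = logging.getLogger(__name__)

CLASS_MATERNAL_DEGRADED = "maternal_degraded"
CLASS_ZYGOTIC_ACTIVATED = "zygotic_activated"
CLASS_STABLE = "stable"


def probe_gene_pairs(annotation: GenomeAnnotation, design: ProbeDesign) -> pd.DataFrame:
    """(probe_id, gene_id) pairs for probes overlapping a gene's exons."""
    rows = []
    for gene in annotation.genes:
        seen: set[str] = set()
        for s, e in gene.exons:
            for p in design.probes_overlapping(Interval(gene.chromosome, s, e)):
                if p.probe_id not in seen:
                    seen.add(p.probe_id)
                    rows.append((p.probe_id, gene.gene_id))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id"])


def replicate_log2fc(
    matrix: IntensityMatrix,
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    conditions: tuple[str, str] = ("unfertilized", "fertilized"),
) -> pd.DataFrame:
    """Per-gene, per-replicate log2 fold change (second condition − first).

    Gene level per column is the median over exon-overlapping probes.  Genes
    without any exon-overlapping probe (untestable) are excluded with a
    logged count.  Dye-swap columns already carry their true condition, so
    the replicate ratio needs no further sign correction.
    """
    ref, alt = conditions
    pairs = probe_gene_pairs(annotation, design)
    n_total = len(annotation.genes)
    pairs = pairs[pairs["probe_id"].isin(matrix.data.index)]
    sub = matrix.data.loc[pairs["probe_id"]]
    sub.index = pd.Index(pairs["gene_id"], name="gene_id")
    gene_medians = sub.groupby(level=0).median()
    n_dropped = n_total - len(gene_medians)
    if n_dropped:
        log.info("excluded %d untestable gene(s) from differential expression", n_dropped)

    reps = sorted({s.replicate for s in matrix.samples})
    cols = {}
    for r in reps:
        ref_cols = [s.name for s in matrix.samples if s.condition == ref and s.replicate == r]
        alt_cols = [s.name for s in matrix.samples if s.condition == alt and s.replicate == r]
        if len(ref_cols) != 1 or len(alt_cols) != 1:
            raise ValueError(
                f"replicate {r} must have exactly one column per condition "
                f"(got {len(ref_cols)} {ref}, {len(alt_cols)} {alt})"
            )
        cols[f"rep{r}"] = gene_medians[alt_cols[0]] - gene_medians[ref_cols[0]]
    return pd.DataFrame(cols)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) from gene-wise sample variances.

    Moments are taken on z = log(s²): under the scaled-F model,
    E z = log(s0²) + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2) and
    Var z = ψ′(d/2) + ψ′(d0/2).  Returns d0 = inf when the observed spread
    of log variances does not exceed the pure-sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive sample variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


@dataclass
class ModeratedTResult:
    t: np.ndarray
    p: np.ndarray
    df_residual: int
    df_prior: float
    s2_prior: float

    @property
    def df_total(self) -> float:
        return self.df_residual + self.df_prior


def moderated_t(
    fold_changes,
    df_prior: float | None = None,
    s2_prior: float | None = None,
) -> ModeratedTResult:
    """One-sample moderated t on per-gene replicate fold changes.

    ``fold_changes`` is genes × replicates.  Hyperparameters are estimated
    from the data unless both overrides are supplied (handy for checking the
    d0 → 0 and d0 → ∞ limits).  With zero variance everywhere the fit is
    impossible and the ordinary one-sample t is used with a warning.
    """
    X = np.asarray(fold_changes, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes × replicates array with ≥2 replicates")
    n_genes, n = X.shape
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    df = n - 1

    if df_prior is None or s2_prior is None:
        if n_genes < 10:
            raise ValueError("need ≥10 genes to estimate the variance prior")
        if np.all(s2 == 0):
            log.warning("all gene variances are zero; falling back to the ordinary t")
            df_prior, s2_prior = 0.0, 0.0
        else:
            df_prior, s2_prior = fit_variance_prior(s2, df)

    if math.isinf(df_prior):
        s2_post = np.full(n_genes, s2_prior)
        df_total = np.inf
    else:
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
        df_total = df + df_prior

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    t = np.where(np.isnan(t), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(t=t, p=p, df_residual=df, df_prior=float(df_prior),
                            s2_prior=float(s2_prior))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    q_(i) = min over j ≥ i of p_(j)·m/j in sorted order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify(
    log2fc,
    q_values,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.1,
) -> np.ndarray:
    """Two-fold classification of differential genes.

    ``maternal_degraded``: q < q_threshold and log2fc ≤ −fc_threshold
    (at least two-fold higher before fertilization); ``zygotic_activated``:
    q < q_threshold and log2fc ≥ +fc_threshold; otherwise ``stable``.
    Fold-change bounds are inclusive ("two-fold or greater").
    """
    fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q_values, dtype=float)
    out = np.full(fc.shape, CLASS_STABLE, dtype=object)
    sig = q < q_threshold
    out[sig & (fc <= -fc_threshold)] = CLASS_MATERNAL_DEGRADED
    out[sig & (fc >= fc_threshold)] = CLASS_ZYGOTIC_ACTIVATED
    return out


def differential_expression_table(
    matrix: IntensityMatrix,
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    conditions: tuple[str, str] = ("unfertilized", "fertilized"),
    fc_threshold: float = 1.0,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Full DE table: gene_id (index), log2fc, t, p, q, de_class."""
    fc = replicate_log2fc(matrix, annotation, design, conditions)
    res = moderated_t(fc.to_numpy())
    q = bh_qvalues(res.p)
    mean_fc = fc.mean(axis=1).to_numpy()
    table = pd.DataFrame(
        {
            "log2fc": mean_fc,
            "t": res.t,
            "p": res.p,
            "q": q,
            "de_class": classify(mean_fc, q, fc_threshold, q_threshold),
        },
        index=fc.index,
    )
    table.index.name = "gene_id"
    return table
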