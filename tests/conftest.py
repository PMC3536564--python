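import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tiletar.annotation_io import (
    Chromosome,
    Gene,
    GenomeAnnotation,
    Interval,
    Probe,
    ProbeDesign,
)
from tiletar.expression_calling import (
    call_genes,
    call_positive,
    condition_thresholds,
    random_probe_baseline,
)
from tiletar.normalization import normalize, summarize_replicates
from tiletar.synthetic_data import SimulationParams, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_annotation():
    """Two chromosomes (one X), three hand-placed genes."""
    chroms = [Chromosome("LG2", 10_000), Chromosome("LGX", 8_000, "X")]
    genes = [
        Gene("g1", "LG2", "+", ((100, 400), (600, 900))),
        Gene("g2", "LG2", "-", ((5_000, 5_310),)),
        Gene("g3", "LGX", "+", ((1_000, 1_300), (1_400, 1_700), (2_000, 2_300))),
    ]
    return GenomeAnnotation(chroms, genes)


def make_design(probes, random_ids=(), length_range=(40, 80)):
    """Small hand-built design: probes as (id, chrom, start, end)."""
    exp = [Probe(pid, "experimental", Interval(c, s, e)) for pid, c, s, e in probes]
    rnd = [Probe(r, "random", None) for r in random_ids]
    return ProbeDesign(exp, rnd, length_range=length_range)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: one synthetic dataset at full size."""
    params = SimulationParams()
    annotation, truth, design, matrix = simulate_dataset(params, seed=7)
    return params, annotation, truth, design, matrix


@pytest.fixture(scope="session")
def default_calls(default_dataset):
    """Normalized, summarized and gene-called version of the default dataset."""
    params, annotation, truth, design, matrix = default_dataset
    norm = normalize(matrix, design)
    summary = summarize_replicates(norm)
    thresholds = condition_thresholds(summary, design)
    baselines = random_probe_baseline(summary, design)
    callsets = call_genes(annotation, design, summary, thresholds, baselines)
    positives = {
        cond: call_positive(summary[cond], thresholds[cond]) for cond in summary.columns
    }
    return {
        "params": params,
        "annotation": annotation,
        "truth": truth,
        "design": design,
        "normalized": norm,
        "summary": summary,
        "thresholds": thresholds,
        "baselines": baselines,
        "callsets": callsets,
        "positives": positives,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
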