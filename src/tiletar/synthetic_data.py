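"""Synthetic tiling-array data with known ground truth.

Emulates the study conditions the analysis assumes: a beetle-like genome of
10 chromosomes (one X) whose genes average 4.4 exons of mean length 310 bp
separated by introns from a short/long mixture (peaks near 57 bp and
1200 bp); an isothermal tiling design of 49–74 bp probes (mean 54 bp)
overlapping 12 bp on average plus an address-less Markov-null random-probe
population; and two-color competitive hybridizations of unfertilized vs
fertilized eggs in three replicates with one dye swap.

Expression structure: a configurable fraction of genes (default 0.582) is
maternally loaded (present in unfertilized eggs and, unless degraded, in
fertilized eggs), a further fraction is zygotic-only, and the rest are
silent.  Intergenic transcriptionally active regions are planted well away
from every gene so the novel-TAR filters can recover them.  Background is
normal on the log2 scale (log-normal raw fluorescence); the expression
effect defaults to +5 log2 units over background, the signal level the
arrays were observed to reach.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    CHROM_AUTOSOME,
    CHROM_X,
    Chromosome,
    Gene,
    GenomeAnnotation,
    Interval,
    Probe,
    ProbeDesign,
)
from .normalization import IntensityMatrix, SampleInfo

CONDITIONS = ("unfertilized", "fertilized")

LABEL_MATERNAL = "maternal"
LABEL_ZYGOTIC_ONLY = "zygotic_only"
LABEL_SILENT = "silent"


@dataclass
class SimulationParams:
    """All knobs of the generator; the defaults are the study conditions."""

    # genome architecture
    n_chromosomes: int = 10
    n_genes: int = 1000
    chromosome_lengths: tuple[int, ...] | None = None  # derived when None
    exons_per_gene_mean: float = 4.4
    exon_length_mean: float = 310.0
    exon_length_min: int = 40
    intron_short_bp: float = 57.0
    intron_long_bp: float = 1200.0
    intron_short_weight: float = 0.75
    intron_sigma: float = 0.35
    intron_min: int = 30
    intergenic_gap_mean: float = 2000.0
    intergenic_gap_min: int = 500
    # probe design
    probe_length_min: int = 49
    probe_length_max: int = 74
    probe_length_mean: float = 54.0
    probe_overlap_mean: float = 12.0
    probe_overlap_sd: float = 3.0
    n_random_probes: int = 10000
    # expression structure
    frac_maternal: float = 0.582
    frac_zygotic_only: float = 0.062
    frac_maternal_degraded: float = 0.10
    degraded_log2fc: float = -2.0
    # planted intergenic TARs (per condition)
    n_planted_tars: int = 40
    tar_shared_fraction: float = 0.5
    tar_length_mean: float = 400.0
    tar_length_min: int = 150
    tar_length_max: int = 1500
    tar_gene_buffer: int = 250
    # signal model (log2 scale)
    background_loc: float = 8.0
    background_scale: float = 0.5
    effect_size: float = 5.0
    probe_affinity_sd: float = 0.4
    replicate_noise: float = 0.25
    array_offset_sd: float = 0.3
    dye_effect: float = 0.3
    min_overlap_frac: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_maternal", "frac_zygotic_only", "frac_maternal_degraded",
                     "tar_shared_fraction", "intron_short_weight", "min_overlap_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_maternal + self.frac_zygotic_only > 1.0:
            raise ValueError("maternal + zygotic-only fractions exceed 1")
        for name in ("exon_length_mean", "intergenic_gap_mean", "tar_length_mean",
                     "probe_overlap_mean", "exons_per_gene_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.probe_length_min <= self.probe_length_max):
            raise ValueError("bad probe length range")
        if self.tar_length_min <= 0 or self.tar_length_min > self.tar_length_max:
            raise ValueError("bad planted-TAR length range")

    @property
    def chromosome_names(self) -> list[str]:
        # beetle convention: one X linkage group plus numbered autosomes
        return ["LGX"] + [f"LG{i}" for i in range(2, self.n_chromosomes + 1)]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["chromosome_lengths"] is not None:
            d["chromosome_lengths"] = list(d["chromosome_lengths"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("chromosome_lengths") is not None:
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted expression labels, fold changes and intergenic TARs."""

    gene_labels: dict[str, str]
    gene_log2fc: dict[str, float]
    planted_tars: dict[str, list[Interval]]

    def label_counts(self) -> dict[str, int]:
        counts = {LABEL_MATERNAL: 0, LABEL_ZYGOTIC_ONLY: 0, LABEL_SILENT: 0}
        for lab in self.gene_labels.values():
            counts[lab] += 1
        return counts

    def expressed_genes(self, condition: str) -> set[str]:
        """Genes carrying signal in the given condition (any level > 0)."""
        out = set()
        for gid, lab in self.gene_labels.items():
            if condition == "unfertilized" and lab == LABEL_MATERNAL:
                out.add(gid)
            elif condition == "fertilized" and lab in (LABEL_MATERNAL, LABEL_ZYGOTIC_ONLY):
                out.add(gid)
        return out


def _rng(params: SimulationParams, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(params.seed if seed is None else seed)


def _draw_exon_lengths(rng, params: SimulationParams, k: int) -> np.ndarray:
    shape = 2.0
    scale = (params.exon_length_mean - params.exon_length_min) / shape
    return params.exon_length_min + np.round(rng.gamma(shape, scale, size=k)).astype(int)


def _draw_intron_lengths(rng, params: SimulationParams, k: int) -> np.ndarray:
    if k == 0:
        return np.zeros(0, dtype=int)
    short = rng.random(k) < params.intron_short_weight
    peaks = np.where(short, params.intron_short_bp, params.intron_long_bp)
    vals = rng.lognormal(np.log(peaks), params.intron_sigma)
    return np.maximum(params.intron_min, np.round(vals)).astype(int)


def _draw_gap(rng, params: SimulationParams) -> int:
    shape = 2.0
    scale = (params.intergenic_gap_mean - params.intergenic_gap_min) / shape
    return int(params.intergenic_gap_min + round(rng.gamma(shape, scale)))


def _gene_counts_per_chromosome(params: SimulationParams) -> list[int]:
    """Deterministic largest-remainder split, weights decreasing with index."""
    w = np.linspace(1.6, 0.6, params.n_chromosomes)
    share = params.n_genes * w / w.sum()
    counts = np.floor(share).astype(int)
    rem = params.n_genes - counts.sum()
    order = np.argsort(-(share - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts.tolist()


def simulate_genome(
    params: SimulationParams, seed: int | None = None
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Simulate a genome annotation plus planted ground truth.

    Genes are laid out sequentially (no overlap) with drawn intergenic gaps;
    when explicit chromosome lengths are given, placement that would overrun
    a chromosome raises an error suggesting larger lengths.  Labels are
    assigned i.i.d. with the configured fractions (the realized counts are
    binomial and recorded in the truth).  Planted TARs occupy intergenic
    gaps with at least ``tar_gene_buffer`` bp clearance from every gene span.
    """
    rng = _rng(params, seed)
    names = params.chromosome_names
    counts = _gene_counts_per_chromosome(params)
    fixed = params.chromosome_lengths
    if fixed is not None and len(fixed) != params.n_chromosomes:
        raise ValueError("chromosome_lengths must have n_chromosomes entries")

    genes: list[Gene] = []
    chromosomes: list[Chromosome] = []
    gaps: list[tuple[str, int, int]] = []  # intergenic (chrom, start, end)
    gene_index = 0
    for ci, (name, n_on_chrom) in enumerate(zip(names, counts)):
        pos = 0
        prev_end = 0
        for _ in range(n_on_chrom):
            gap = _draw_gap(rng, params)
            start = pos + gap
            k = 1 + rng.poisson(max(0.0, params.exons_per_gene_mean - 1.0))
            exon_lens = _draw_exon_lengths(rng, params, k)
            intron_lens = _draw_intron_lengths(rng, params, k - 1)
            exons = []
            cursor = start
            for i, el in enumerate(exon_lens):
                exons.append((cursor, cursor + int(el)))
                cursor += int(el)
                if i < k - 1:
                    cursor += int(intron_lens[i])
            if fixed is not None and cursor > fixed[ci]:
                raise ValueError(
                    f"chromosome {name} (length {fixed[ci]}) too small for the "
                    "requested genes; increase chromosome lengths or reduce n_genes"
                )
            gene_index += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"TCSIM{gene_index:06d}", name, strand, tuple(exons)))
            gaps.append((name, prev_end, start))
            prev_end = cursor
            pos = cursor
        terminal_gap = _draw_gap(rng, params)
        length = fixed[ci] if fixed is not None else pos + terminal_gap
        gaps.append((name, prev_end, length))
        chrom_class = CHROM_X if name == "LGX" else CHROM_AUTOSOME
        chromosomes.append(Chromosome(name, length, chrom_class))

    # expression labels, i.i.d. with the configured fractions
    labels: dict[str, str] = {}
    log2fc: dict[str, float] = {}
    u = rng.random(len(genes))
    v = rng.random(len(genes))
    for g, ug, vg in zip(genes, u, v):
        if ug < params.frac_maternal:
            labels[g.gene_id] = LABEL_MATERNAL
            log2fc[g.gene_id] = (
                params.degraded_log2fc if vg < params.frac_maternal_degraded else 0.0
            )
        elif ug < params.frac_maternal + params.frac_zygotic_only:
            labels[g.gene_id] = LABEL_ZYGOTIC_ONLY
            log2fc[g.gene_id] = params.effect_size
        else:
            labels[g.gene_id] = LABEL_SILENT
            log2fc[g.gene_id] = 0.0

    planted = _plant_tars(rng, params, gaps)
    truth = GroundTruth(labels, log2fc, planted)
    return GenomeAnnotation(chromosomes, genes), truth


def _plant_tars(
    rng, params: SimulationParams, gaps: list[tuple[str, int, int]]
) -> dict[str, list[Interval]]:
    n_shared = int(round(params.n_planted_tars * params.tar_shared_fraction))
    n_unique = params.n_planted_tars - n_shared
    n_total = n_shared + 2 * n_unique
    planted: dict[str, list[Interval]] = {c: [] for c in CONDITIONS}
    if n_total == 0:
        return planted

    lengths = np.clip(
        np.round(rng.lognormal(np.log(params.tar_length_mean), 0.4, size=n_total)),
        params.tar_length_min,
        params.tar_length_max,
    ).astype(int)
    buf = params.tar_gene_buffer
    usable = [
        (chrom, s + buf, e - buf)
        for chrom, s, e in gaps
        if (e - buf) - (s + buf) >= int(lengths.max())
    ]
    if len(usable) < n_total:
        raise ValueError(
            f"only {len(usable)} intergenic gaps can host planted TARs; "
            f"need {n_total} — enlarge intergenic gaps or reduce n_planted_tars"
        )
    chosen = rng.choice(len(usable), size=n_total, replace=False)
    intervals: list[Interval] = []
    for idx, length in zip(chosen, lengths):
        chrom, lo, hi = usable[idx]
        start = int(lo + rng.integers(0, hi - lo - length + 1))
        intervals.append(Interval(chrom, start, start + int(length)))

    for i, iv in enumerate(intervals):
        if i < n_shared:
            planted["unfertilized"].append(iv)
            planted["fertilized"].append(iv)
        elif i < n_shared + n_unique:
            planted["unfertilized"].append(iv)
        else:
            planted["fertilized"].append(iv)
    for lst in planted.values():
        lst.sort(key=lambda iv: (iv.chromosome, iv.start))
    return planted


def design_probes(
    annotation: GenomeAnnotation, params: SimulationParams, seed: int | None = None
) -> ProbeDesign:
    """Tile every chromosome end to end, then append the random-null probes.

    Probe lengths are drawn with mean ≈ ``probe_length_mean`` within the
    design range; the step to the next probe is length − overlap with
    overlap ~ N(12, sd) rounded and clipped, so successive probes overlap
    12 bp on average.  The final probe of a chromosome is shifted left to
    end exactly at the chromosome end.
    """
    rng = _rng(params, seed)
    experimental: list[Probe] = []
    i = 0
    shape = 2.0
    scale = (params.probe_length_mean - params.probe_length_min) / shape
    for chrom in annotation.chromosomes:
        L = chrom.length
        pos = 0
        prev_start = -1
        while pos < L:
            length = int(
                np.clip(
                    params.probe_length_min + round(rng.gamma(shape, scale)),
                    params.probe_length_min,
                    params.probe_length_max,
                )
            )
            start = pos
            if start + length > L:
                # right-align the final probe so tiling ends exactly at the
                # chromosome end; shorten it if it would precede the previous
                start = L - length
                if start <= prev_start:
                    length = min(params.probe_length_max, L - prev_start - 1)
                    start = L - length
                    if length < params.probe_length_min:
                        break
            i += 1
            experimental.append(
                Probe(f"P{i:07d}", "experimental",
                      Interval(chrom.name, start, start + length))
            )
            prev_start = start
            if start + length >= L:
                break
            overlap = int(
                np.clip(
                    round(rng.normal(params.probe_overlap_mean, params.probe_overlap_sd)),
                    1,
                    length - 1,
                )
            )
            pos = start + length - overlap
    random = [Probe(f"RND{j:06d}", "random", None) for j in range(1, params.n_random_probes + 1)]
    return ProbeDesign(
        experimental, random,
        length_range=(params.probe_length_min, params.probe_length_max),
    )


def _condition_features(
    truth: GroundTruth, annotation: GenomeAnnotation, params: SimulationParams,
    condition: str,
) -> dict[str, list[tuple[int, int, float, int]]]:
    """Per chromosome: (start, end, effect_level, feature_group) pieces.

    Exons of one gene share a feature_group so a probe's overlap fraction is
    computed against the gene's whole exonic footprint (a probe spanning a
    short intron accumulates overlap from both flanking exons).
    """
    feats: dict[str, list[tuple[int, int, float, int]]] = {}
    group = 0
    for g in annotation.genes:
        lab = truth.gene_labels[g.gene_id]
        fc = truth.gene_log2fc[g.gene_id]
        if lab == LABEL_MATERNAL:
            level = params.effect_size if condition == "unfertilized" else params.effect_size + fc
        elif lab == LABEL_ZYGOTIC_ONLY:
            level = 0.0 if condition == "unfertilized" else params.effect_size
        else:
            level = 0.0
        if level <= 0.0:
            continue
        group += 1
        for s, e in g.exons:
            feats.setdefault(g.chromosome, []).append((s, e, level, group))
    for iv in truth.planted_tars.get(condition, []):
        group += 1
        feats.setdefault(iv.chromosome, []).append(
            (iv.start, iv.end, params.effect_size, group)
        )
    for lst in feats.values():
        lst.sort()
    return feats


def _probe_effects(
    design: ProbeDesign, feats: dict[str, list[tuple[int, int, float, int]]],
    params: SimulationParams,
) -> np.ndarray:
    """Expression effect per experimental probe for one condition.

    A probe responds to a feature group when ≥ ``min_overlap_frac`` of it
    lies inside the group's footprint; the effect is the group level scaled
    by the overlap fraction, and overlapping groups contribute their max.
    """
    effects = np.zeros(len(design.experimental))
    # per-chromosome sweep: features sorted by start, probes sorted by start
    chrom_feats = {c: lst for c, lst in feats.items()}
    probe_pos: dict[str, list[tuple[int, int, int]]] = {}
    for idx, p in enumerate(design.experimental):
        a = p.address
        probe_pos.setdefault(a.chromosome, []).append((a.start, a.end, idx))
    import bisect as _bisect

    for chrom, plist in probe_pos.items():
        flist = chrom_feats.get(chrom)
        if not flist:
            continue
        starts = [f[0] for f in flist]
        max_flen = max(fe - fs for fs, fe, _, _ in flist)
        for s, e, idx in plist:
            # features sorted by start; only those starting within one
            # feature-length of the probe can overlap it
            lo = _bisect.bisect_left(starts, s - max_flen)
            hi = _bisect.bisect_left(starts, e)
            by_group: dict[int, float] = {}
            by_level: dict[int, float] = {}
            for fs, fe, level, grp in flist[lo:hi]:
                ov = min(e, fe) - max(s, fs)
                if ov > 0:
                    by_group[grp] = by_group.get(grp, 0) + ov
                    by_level[grp] = level
            best = 0.0
            plen = e - s
            for grp, ov in by_group.items():
                frac = ov / plen
                if frac >= params.min_overlap_frac:
                    best = max(best, by_level[grp] * frac)
            effects[idx] = best
    return effects


def simulate_intensities(
    truth: GroundTruth,
    design: ProbeDesign,
    annotation: GenomeAnnotation,
    params: SimulationParams,
    seed: int | None = None,
) -> IntensityMatrix:
    """Simulate the probe × sample log2 fluorescence matrix.

    Each value is background location + per-probe affinity + per-array offset
    + dye offset + expression effect (experimental probes overlapping an
    expressed feature of the channel's condition) + replicate noise.  Random
    probes draw from the background components only.  The last replicate is
    the dye swap: its condition↔dye pairing is reversed and flagged.
    """
    rng = _rng(params, seed)
    n_exp = len(design.experimental)
    n_rnd = len(design.random)
    n_probes = n_exp + n_rnd

    effects = {
        cond: _probe_effects(
            design, _condition_features(truth, annotation, params, cond), params
        )
        for cond in CONDITIONS
    }

    samples: list[SampleInfo] = []
    for r in range(1, params.n_replicates + 1):
        swapped = r == params.n_replicates  # single dye swap on the last replicate
        dye_of = (
            {"fertilized": "cy3", "unfertilized": "cy5"}
            if swapped
            else {"unfertilized": "cy3", "fertilized": "cy5"}
        )
        for cond in CONDITIONS:
            samples.append(SampleInfo(cond, r, dye_of[cond], swapped))

    affinity = rng.normal(0.0, params.probe_affinity_sd, size=n_probes)
    values = np.empty((n_probes, len(samples)))
    for j, s in enumerate(samples):
        array_offset = rng.normal(0.0, params.array_offset_sd)
        dye_offset = params.dye_effect / 2.0 if s.dye == "cy5" else -params.dye_effect / 2.0
        noise = rng.normal(0.0, params.replicate_noise, size=n_probes)
        col = params.background_loc + affinity + array_offset + dye_offset + noise
        col[:n_exp] += effects[s.condition]
        values[:, j] = col

    index = pd.Index(design.experimental_ids + design.random_ids, name="probe_id")
    data = pd.DataFrame(values, index=index, columns=[s.name for s in samples])
    return IntensityMatrix(data, samples)


def simulate_dataset(
    params: SimulationParams, seed: int | None = None
) -> tuple[GenomeAnnotation, GroundTruth, ProbeDesign, IntensityMatrix]:
    """Convenience wrapper: genome → probes → intensities with one seed.

    Sub-seeds for the three stages are derived deterministically from the
    master seed, so each stage is reproducible on its own as well.
    """
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    annotation, truth = simulate_genome(params, seeds[0])
    design = design_probes(annotation, params, seeds[1])
    matrix = simulate_intensities(truth, design, annotation, params, seeds[2])
    return annotation, truth, design, matrix


# ---------------------------------------------------------------------------
# Truth serialization (TSV, for pipeline runs)


def write_ground_truth(truth: GroundTruth, genes_path: str | Path, tars_path: str | Path) -> None:
    rows = [
        (gid, truth.gene_labels[gid], truth.gene_log2fc[gid])
        for gid in sorted(truth.gene_labels)
    ]
    pd.DataFrame(rows, columns=["gene_id", "label", "log2fc"]).to_csv(
        genes_path, sep="\t", index=False
    )
    trows = [
        (cond, iv.chromosome, iv.start, iv.end)
        for cond in sorted(truth.planted_tars)
        for iv in truth.planted_tars[cond]
    ]
    pd.DataFrame(trows, columns=["condition", "chromosome", "start", "end"]).to_csv(
        tars_path, sep="\t", index=False
    )


def read_ground_truth(genes_path: str | Path, tars_path: str | Path) -> GroundTruth:
    g = pd.read_csv(genes_path, sep="\t")
    t = pd.read_csv(tars_path, sep="\t")
    labels = dict(zip(g["gene_id"], g["label"]))
    fc = dict(zip(g["gene_id"], g["log2fc"].astype(float)))
    planted: dict[str, list[Interval]] = {c: [] for c in CONDITIONS}
    for _, row in t.iterrows():
        planted.setdefault(row["condition"], []).append(
            Interval(row["chromosome"], int(row["start"]), int(row["end"]))
        )
    return GroundTruth(labels, fc, planted)
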