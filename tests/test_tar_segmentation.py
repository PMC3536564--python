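import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_design
from tiletar.annotation_io import Chromosome, Gene, GenomeAnnotation, Interval
from tiletar.comparative_stats import pearson_r
from tiletar.tar_segmentation import (
    TAR,
    estimate_novel_genes,
    filter_novel,
    match_planted,
    segment_tars,
    tar_chromosome_counts,
    tar_size_distribution,
    unique_tars,
)


def tiled_design(n, chrom="c", start0=0, length=54, step=42):
    return make_design(
        [(f"p{i}", chrom, start0 + i * step, start0 + i * step + length) for i in range(n)]
    )


def positives_from(design, flags):
    return pd.Series(dict(zip((p.probe_id for p in design.experimental), flags)))


def brute_force_tars(positives, design, minrun=45, maxgap=0, min_probes=3):
    """Independent oracle: enumerate all maximal positive runs, then filter."""
    probes = design.experimental
    runs, current = [], []
    for p in probes:
        ok = bool(positives.get(p.probe_id, False))
        if current:
            prev = current[-1].address
            contiguous = (
                p.address.chromosome == prev.chromosome
                and p.address.start - prev.end <= maxgap
            )
            if not (ok and contiguous):
                runs.append(current)
                current = []
        if ok:
            current.append(p)
    if current:
        runs.append(current)
    out = []
    for run in runs:
        if len(run) < min_probes:
            continue
        span = run[-1].address.midpoint - run[0].address.midpoint
        if span >= minrun:
            out.append((run[0].address.chromosome, run[0].address.start,
                        run[-1].address.end, len(run)))
    return out


def as_tuples(tars):
    return [(t.interval.chromosome, t.interval.start, t.interval.end, t.n_probes)
            for t in tars]


class TestSegmentTars:
    def test_three_adjacent_probes(self):
        design = tiled_design(3)
        tars = segment_tars(positives_from(design, [True] * 3), design)
        assert len(tars) == 1
        t = tars[0]
        assert (t.interval.start, t.interval.end) == (0, 138)
        assert t.midpoint_span == 84 and t.n_probes == 3

    def test_two_probes_insufficient(self):
        design = tiled_design(2)
        assert segment_tars(positives_from(design, [True, True]), design) == []

    def test_intermittent_negative_breaks_run(self):
        design = tiled_design(5)
        flags = [True, False, True, True, True]
        tars = segment_tars(positives_from(design, flags), design)
        assert len(tars) == 1
        assert tars[0].interval.start == design.experimental[2].address.start
        assert tars[0].n_probes == 3

    def test_no_positive_probes(self):
        design = tiled_design(4)
        assert segment_tars(positives_from(design, [False] * 4), design) == []

    def test_physical_tiling_gap_breaks_run(self):
        """Design-consecutive probes separated by untiled sequence never join."""
        design = make_design(
            [("p0", "c", 0, 54), ("p1", "c", 42, 96),
             ("p2", "c", 300, 354), ("p3", "c", 342, 396), ("p4", "c", 384, 438)]
        )
        tars = segment_tars(positives_from(design, [True] * 5), design)
        assert as_tuples(tars) == [("c", 300, 438, 3)]

    def test_chromosome_boundary_breaks_run(self):
        design = make_design(
            [("a1", "c1", 0, 54), ("a2", "c1", 42, 96), ("a3", "c1", 84, 138),
             ("b1", "c2", 0, 54), ("b2", "c2", 42, 96), ("b3", "c2", 84, 138)]
        )
        tars = segment_tars(positives_from(design, [True] * 6), design)
        assert [t.interval.chromosome for t in tars] == ["c1", "c2"]

    def test_mean_signal_over_baseline(self):
        design = tiled_design(3)
        pos = positives_from(design, [True] * 3)
        values = pd.Series({"p0": 12.0, "p1": 13.0, "p2": 14.0})
        tars = segment_tars(pos, design, values, baseline=8.0)
        assert tars[0].mean_signal == pytest.approx(5.0)

    @given(st.lists(st.booleans(), min_size=1, max_size=60), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, flags, seed):
        rng = np.random.default_rng(seed)
        # random geometry: mixed lengths, occasional tiling gaps
        probes, pos = [], 0
        for i in range(len(flags)):
            length = int(rng.integers(49, 75))
            probes.append((f"p{i}", "c", pos, pos + length))
            pos += length - int(rng.integers(-30, 13))  # step may exceed length
        design = make_design(probes)
        positives = positives_from(design, flags)
        assert as_tuples(segment_tars(positives, design)) == brute_force_tars(
            positives, design
        )


class TestFilterNovel:
    def _annotation(self):
        return GenomeAnnotation(
            [Chromosome("c", 100_000)],
            [Gene("g", "c", "+", ((10_000, 10_500), (11_000, 12_000)))],
        )

    def _tar(self, start, end):
        return TAR("t", "u", Interval("c", start, end), 3, 84.0, 1.0)

    def test_length_exactly_min_removed(self):
        ann = self._annotation()
        assert filter_novel([self._tar(50_000, 50_100)], ann) == []
        assert len(filter_novel([self._tar(50_000, 50_101)], ann)) == 1

    def test_distance_boundary_strict(self):
        ann = self._annotation()  # gene span [10000, 12000)
        exactly_100 = self._tar(12_100, 12_300)  # gap = 100 → removed
        assert filter_novel([exactly_100], ann) == []
        just_past = self._tar(12_101, 12_301)  # gap = 101 → kept
        assert len(filter_novel([just_past], ann)) == 1

    def test_gene_overlap_removed(self):
        ann = self._annotation()
        assert filter_novel([self._tar(10_900, 11_200)], ann) == []

    def test_upstream_distance_checked(self):
        ann = self._annotation()
        assert filter_novel([self._tar(9_700, 9_900)], ann) == []  # gap 100 upstream
        assert len(filter_novel([self._tar(9_600, 9_899)], ann)) == 1

    def test_monotone_in_thresholds(self):
        ann = self._annotation()
        tars = [self._tar(s, s + ln) for s, ln in
                [(13_000, 150), (12_150, 400), (50_000, 101), (9_000, 200)]]
        base = {t.id for t in filter_novel(tars, ann)}
        for min_len, min_dist in [(150, 100), (100, 500), (300, 1000)]:
            stricter = {t.id for t in filter_novel(tars, ann, min_len, min_dist)}
            assert stricter <= {t.id for t in filter_novel(tars, ann, 100, 100)}


class TestUniqueTars:
    def _tars(self, spec, cond="u"):
        return [TAR(f"{cond}{i}", cond, Interval("c", s, e), 3, 84.0, 1.0)
                for i, (s, e) in enumerate(spec)]

    def test_disjoint_sets(self):
        a = self._tars([(0, 100), (200, 300)])
        b = self._tars([(400, 500)], "f")
        assert unique_tars(a, b) == a

    def test_identical_sets(self):
        a = self._tars([(0, 100)])
        assert unique_tars(a, a) == []

    def test_single_bp_overlap_excluded(self):
        a = self._tars([(0, 100)])
        b = self._tars([(99, 200)], "f")
        assert unique_tars(a, b) == []
        b_abut = self._tars([(100, 200)], "f")
        assert unique_tars(a, b_abut) == a

    def test_unique_and_overlapping_partition(self):
        a = self._tars([(0, 100), (150, 250), (300, 400), (500, 600)])
        b = self._tars([(90, 160), (350, 380)], "f")
        uniq = unique_tars(a, b)
        overlapping = [t for t in a if t not in uniq]
        assert {t.id for t in uniq} | {t.id for t in overlapping} == {t.id for t in a}
        assert all(any(t.interval.overlaps(o.interval) for o in b) for t in overlapping)


class TestEstimateNovelGenes:
    @pytest.mark.parametrize("n,expected", [(2315, 526), (4060, 922), (0, 0), (44, 10)])
    def test_floor_counts(self, n, expected):
        assert estimate_novel_genes(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            estimate_novel_genes(-1)


class TestTarDistributions:
    def _tars(self, lengths):
        return [TAR(f"t{i}", "u", Interval("c", 1000 * i, 1000 * i + ln), 3, 84.0, 1.0)
                for i, ln in enumerate(lengths)]

    def test_single_bin(self):
        h = tar_size_distribution(self._tars([110, 120, 130]), [100, 200])
        assert h["count"].tolist() == [3]
        assert h["fraction"].tolist() == [1.0]

    def test_fractions_sum_to_one(self, rng):
        lengths = rng.integers(101, 900, size=50)
        h = tar_size_distribution(self._tars(lengths), np.arange(100, 1000, 100))
        assert h["fraction"].sum() == pytest.approx(1.0)

    def test_bins_must_cover_range(self):
        with pytest.raises(ValueError):
            tar_size_distribution(self._tars([500]), [100, 200])

    def test_chromosome_counts_conserved(self, toy_annotation):
        tars = [TAR("t1", "u", Interval("LG2", 0, 200), 3, 84.0, 1.0),
                TAR("t2", "u", Interval("LG2", 900, 1100), 3, 84.0, 1.0),
                TAR("t3", "u", Interval("LGX", 0, 200), 3, 84.0, 1.0)]
        counts = tar_chromosome_counts(tars, toy_annotation)
        assert counts["n_tars"].sum() == 3
        assert counts.set_index("chromosome").loc["LG2", "n_tars"] == 2

    def test_uniform_placement_tracks_chromosome_length(self, rng):
        """TARs placed uniformly per bp correlate strongly with length."""
        lengths = np.linspace(2e6, 8e6, 10).astype(int)
        ann = GenomeAnnotation(
            [Chromosome(f"LG{i + 2}", int(L)) for i, L in enumerate(lengths)], []
        )
        names = [c.name for c in ann.chromosomes]  # lexicographic order
        sorted_lengths = np.array([c.length for c in ann.chromosomes])
        probs = sorted_lengths / sorted_lengths.sum()
        tars = []
        for i in range(400):
            chrom = rng.choice(len(names), p=probs)
            start = int(rng.integers(0, sorted_lengths[chrom] - 200))
            tars.append(TAR(f"t{i}", "u", Interval(names[chrom], start, start + 200),
                            3, 84.0, 1.0))
        counts = tar_chromosome_counts(tars, ann)
        assert pearson_r(counts["n_tars"], counts["length"]) >= 0.9


class TestPlantedRecovery:
    def test_precision_and_recall_on_default_data(self, default_calls):
        from tiletar.tar_segmentation import filter_novel, segment_tars

        for cond in ("unfertilized", "fertilized"):
            segs = segment_tars(
                default_calls["positives"][cond], default_calls["design"],
                default_calls["summary"][cond], default_calls["baselines"][cond], cond,
            )
            novel = filter_novel(segs, default_calls["annotation"])
            precision, recall = match_planted(
                novel, default_calls["truth"].planted_tars[cond]
            )
            assert precision >= 0.9
            assert recall >= 0.9
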