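import numpy as np
import pandas as pd
import pytest

from granatum.intervals import Interval, IntervalSet, interval_span
from granatum.sweeps import (
    candidate_divergent_region,
    classify_accessions,
    genes_in_regions,
    ref_genotype_proportion,
    sweep_overlap,
    top_fraction_windows,
)
from granatum.variant_io import GenomeLayout, GenomicWindow, GenotypeMatrix, MISSING


def _stats(values, size=20_000, step=2_000, chrom="chr1"):
    starts = np.arange(len(values)) * step
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + size,
            "n_sites": 10,
            "statistic": "fst",
            "value": values,
        }
    )


class TestTopFraction:
    def test_distinct_scores_select_exact_fraction(self):
        stats = _stats(np.arange(100, dtype=float))
        sel, regions = top_fraction_windows(stats, 0.05)
        assert len(sel) == 5
        assert set(sel["value"]) == {95.0, 96.0, 97.0, 98.0, 99.0}

    def test_adjacent_windows_union_into_one_sweep(self):
        # 3 consecutive selected 20-kb windows at 2-kb step span 24 kb
        values = np.zeros(100)
        values[50:53] = [10.0, 11.0, 12.0]
        values[:50] = np.linspace(0, 1, 50)  # distinct low scores
        _, regions = top_fraction_windows(_stats(values), 0.03)
        assert len(regions) == 1
        iv = regions.intervals[0]
        assert iv.end - iv.start == 24_000

    def test_ties_at_threshold_all_kept(self):
        values = np.r_[np.zeros(90), np.full(10, 5.0)]
        sel, _ = top_fraction_windows(_stats(values), 0.05)
        assert len(sel) == 10  # all tied windows kept, superset allowed

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(3)
        stats = _stats(rng.random(200))
        s1, _ = top_fraction_windows(stats, 0.05)
        s2, _ = top_fraction_windows(stats, 0.20)
        assert set(s1["start"]) <= set(s2["start"])

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_windows(_stats([np.nan] * 30), 0.05)


class TestSweepOverlap:
    genome = GenomeLayout((("chr1", 1_000_000),))

    def test_identity_and_disjoint(self):
        a = IntervalSet([("chr1", 0, 100_000)])
        b = IntervalSet([("chr1", 500_000, 600_000)])
        assert sweep_overlap(a, a, self.genome)[1] == 100.0
        assert sweep_overlap(a, b, self.genome)[0] == 0

    def test_genome_fractions(self):
        a = IntervalSet([("chr1", 0, 250_000)])
        b = IntervalSet([("chr1", 100_000, 200_000)])
        bp, pct_a, ga, gb = sweep_overlap(a, b, self.genome)
        assert (bp, pct_a) == (100_000, 40.0)
        assert (ga, gb) == (25.0, 10.0)


class TestGenesInRegions:
    regions = IntervalSet([("chr1", 1_000, 2_000), ("chr2", 0, 500)])

    def test_containment_and_exclusion(self):
        genes = [("g1", "chr1", 1_200, 1_300), ("g2", "chr1", 5_000, 6_000)]
        assert genes_in_regions(genes, self.regions) == ["g1"]

    def test_one_bp_overlap_counts(self):
        genes = [("g1", "chr1", 1_999, 3_000), ("g2", "chr1", 2_000, 3_000)]
        assert genes_in_regions(genes, self.regions) == ["g1"]

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(8)
        genes = [
            (f"g{i}", "chr1", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 10_000, 200), rng.integers(1, 500, 200))
            )
        ]
        regions = IntervalSet(
            [("chr1", int(s), int(s) + 300) for s in rng.integers(0, 10_000, 10)]
        )
        expected = [
            gid
            for gid, c, s, e in genes
            if any(
                iv.chrom == c and s < iv.end and e > iv.start for iv in regions
            )
        ]
        assert genes_in_regions(genes, regions) == expected


class TestRefProportion:
    def _matrix(self, codes):
        codes = np.asarray(codes, dtype=np.int8)
        return GenotypeMatrix(
            [f"s{i}" for i in range(codes.shape[0])],
            ["chr1"] * codes.shape[1],
            np.arange(codes.shape[1]) * 10,
            ["A"] * codes.shape[1],
            ["T"] * codes.shape[1],
            codes,
        )

    def test_extremes(self):
        m = self._matrix(np.r_[np.zeros((1, 10)), np.full((1, 10), 2)])
        prof = ref_genotype_proportion(m, [GenomicWindow("chr1", 0, 100)])
        by = prof.set_index("sample")["ref_prop"]
        assert by["s0"] == 1.0 and by["s1"] == 0.0

    def test_mixed_count(self):
        row = [0] * 8 + [1, 2]
        prof = ref_genotype_proportion(
            self._matrix([row]), [GenomicWindow("chr1", 0, 100)]
        )
        assert prof["ref_prop"][0] == pytest.approx(0.8)

    def test_het_counts_as_nonreference(self):
        prof = ref_genotype_proportion(
            self._matrix([[1] * 10]), [GenomicWindow("chr1", 0, 100)]
        )
        assert prof["ref_prop"][0] == 0.0

    def test_empty_window_nan(self):
        prof = ref_genotype_proportion(
            self._matrix([[0, 0]]), [GenomicWindow("chr1", 1_000, 2_000)]
        )
        assert np.isnan(prof["ref_prop"][0])


def _profiles(tracks: dict, size=100_000):
    rows = []
    for sample, values in tracks.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "sample": sample, "chrom": "chr1", "start": i * size,
                    "end": (i + 1) * size, "n_sites": 10, "ref_prop": v,
                }
            )
    return pd.DataFrame(rows)


class TestClassify:
    def test_constructed_profiles(self):
        prof = _profiles(
            {"hi": [0.9] * 5, "lo": [0.1] * 5, "mix": [0.9, 0.1, 0.9, 0.9, 0.9]}
        )
        cls = classify_accessions(prof, ("chr1", 0, 500_000))
        assert cls["hi"] == "reference_like"
        assert cls["lo"] == "divergent"
        assert cls["mix"] == "ambiguous"

    def test_boundaries_inclusive(self):
        prof = _profiles({"a": [0.8, 0.8], "b": [0.2, 0.2]})
        cls = classify_accessions(prof, ("chr1", 0, 200_000))
        assert cls["a"] == "reference_like" and cls["b"] == "divergent"


class TestDivergentRegion:
    def test_no_divergence_gives_empty_set(self):
        prof = _profiles({"a": [0.5] * 10, "b": [0.5] * 10})
        out = candidate_divergent_region(prof, {"a": "p1", "b": "p2"})
        assert len(out) == 0

    def test_impossible_threshold_empty(self):
        prof = _profiles({"a": [0.9] * 10, "b": [0.1] * 10})
        out = candidate_divergent_region(prof, {"a": "p1", "b": "p2"}, threshold=1.0)
        assert len(out) == 0

    def test_gap_bridging(self):
        a = [0.9] * 3 + [0.5] + [0.9] * 3 + [0.5] * 5 + [0.9] * 2
        b = [0.1] * 3 + [0.5] + [0.1] * 3 + [0.5] * 5 + [0.1] * 2
        out = candidate_divergent_region(
            _profiles({"a": a, "b": b}), {"a": "p1", "b": "p2"}, max_gap_windows=2
        )
        # one gap window bridged; the 5-window gap splits the runs
        assert [(iv.start, iv.end) for iv in out] == [
            (0, 700_000),
            (1_200_000, 1_400_000),
        ]


class TestSpanArithmetic:
    def test_reported_primary_inversion_span(self):
        assert interval_span(18_658_790, 24_069_667) == 5_410_877

    def test_reported_second_inversion_span(self):
        assert interval_span(36_776_860, 38_211_514) == 1_434_654
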