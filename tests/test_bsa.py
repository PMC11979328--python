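import math

import numpy as np
import pandas as pd
import pytest

import oracles
from granatum import bsa
from granatum.intervals import IntervalSet
from granatum.variant_io import GenomeLayout


def _counts(rows):
    """rows: (chrom, pos, ref, alt, {base_1: n}, {base_2: n})"""
    recs = []
    for chrom, pos, ref, alt, p1, p2 in rows:
        rec = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for b in "ACGT":
            rec[f"{b}_1"] = p1.get(b, 0)
            rec[f"{b}_2"] = p2.get(b, 0)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(10, 0, 0.0), (0, 10, 1.0), (5, 15, 0.75)]
    )
    def test_values(self, ref, alt, expected):
        assert bsa.snp_index(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_nan(self):
        assert np.isnan(bsa.snp_index(0, 0))


class TestSiteStats:
    def test_ed_extremes(self):
        df = _counts(
            [
                ("chr1", 100, "A", "T", {"A": 10}, {"T": 10}),   # maximal divergence
                ("chr1", 200, "A", "T", {"A": 5, "T": 5}, {"A": 10, "T": 10}),
            ]
        )
        st = bsa.site_stats(df)
        assert st["ed"][0] == pytest.approx(math.sqrt(2), rel=1e-12)
        assert st["ed2"][0] == pytest.approx(2.0, rel=1e-12)
        assert st["ed"][1] == pytest.approx(0.0, abs=1e-12)

    def test_ed_worked_example(self):
        df = _counts([("chr1", 100, "A", "T", {"A": 6, "T": 4}, {"A": 2, "T": 8})])
        st = bsa.site_stats(df)
        assert st["ed"][0] == pytest.approx(math.sqrt(0.4**2 + 0.4**2), rel=1e-9)
        assert st["ed"][0] == pytest.approx(
            oracles.euclidean_distance({"A": 6, "T": 4}, {"A": 2, "T": 8}), rel=1e-9
        )

    def test_min_depth_filter(self):
        df = _counts(
            [
                ("chr1", 100, "A", "T", {"A": 3}, {"A": 50}),
                ("chr1", 200, "A", "T", {"A": 30}, {"A": 50}),
            ]
        )
        assert list(bsa.site_stats(df, min_depth=4)["pos"]) == [200]

    def test_pool_swap_invariance(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            p1 = {b: int(rng.integers(0, 30)) for b in "ACGT"}
            p2 = {b: int(rng.integers(0, 30)) for b in "ACGT"}
            rows.append(("chr1", 100 + i, "A", "T", p1, p2))
        df = _counts(rows)
        swapped = df.rename(
            columns={
                **{f"{b}_1": f"{b}_2" for b in "ACGT"},
                **{f"{b}_2": f"{b}_1" for b in "ACGT"},
            }
        )
        s1 = bsa.site_stats(df)
        s2 = bsa.site_stats(swapped)
        np.testing.assert_allclose(s1["ed"], s2["ed"])
        np.testing.assert_allclose(s1["delta_snp_index"], s2["delta_snp_index"])

    def test_base_relabel_invariance(self):
        # permuting base labels consistently in both pools preserves ED
        df = _counts([("chr1", 100, "A", "G", {"A": 12, "G": 8}, {"A": 3, "G": 17})])
        perm = _counts([("chr1", 100, "C", "T", {"C": 12, "T": 8}, {"C": 3, "T": 17})])
        assert bsa.site_stats(df)["ed"][0] == pytest.approx(
            bsa.site_stats(perm)["ed"][0], rel=1e-12
        )

    def test_ranges(self):
        rng = np.random.default_rng(1)
        rows = [
            (
                "chr1", 100 + i, "A", "T",
                {b: int(rng.integers(0, 40)) for b in "ACGT"},
                {b: int(rng.integers(0, 40)) for b in "ACGT"},
            )
            for i in range(100)
        ]
        st = bsa.site_stats(_counts(rows))
        assert ((st["ed"] >= 0) & (st["ed"] <= math.sqrt(2) + 1e-12)).all()
        assert ((st["ed2"] >= 0) & (st["ed2"] <= 2 + 1e-12)).all()
        np.testing.assert_allclose(st["ed2"], st["ed"] ** 2)
        np.testing.assert_allclose(
            st["delta_snp_index"], (st["snp_index_1"] - st["snp_index_2"]).abs()
        )


class TestLowIndexFilter:
    def test_rules(self):
        st = pd.DataFrame(
            {
                "snp_index_1": [0.2, 0.2, 0.3],
                "snp_index_2": [0.25, 0.5, 0.3],
            }
        )
        kept = bsa.filter_low_index(st)
        # (0.2, 0.25) removed: both below; (0.2, 0.5) kept; (0.3, 0.3) kept (strict <)
        assert list(kept["snp_index_2"]) == [0.5, 0.3]


class TestWindowSmooth:
    layout = GenomeLayout((("chr1", 1_000_000),))

    def test_constant_values(self):
        st = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(0, 1_000_000, 5_000), "x": 0.7}
        )
        out = bsa.window_smooth(st, "x", self.layout)
        assert np.allclose(out["value"], 0.7)

    def test_empty_window_nan(self):
        st = pd.DataFrame({"chrom": ["chr1"], "pos": [999_999], "x": [1.0]})
        out = bsa.window_smooth(st, "x", self.layout)
        assert np.isnan(out["value"][0]) and out["value"].notna().any()

    def test_matches_bruteforce_means(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(1_000_000, 300, replace=False))
        st = pd.DataFrame({"chrom": "chr1", "pos": pos, "x": rng.random(300)})
        out = bsa.window_smooth(st, "x", self.layout, size=100_000, step=30_000)
        for row in out.itertuples():
            exp = oracles.window_mean(pos, st["x"], row.start, row.end)
            if math.isnan(exp):
                assert math.isnan(row.value)
            else:
                assert row.value == pytest.approx(exp, rel=1e-9)


class TestDeltaWindows:
    layout = GenomeLayout((("chr1", 500_000),))

    def test_site_delta_equals_smoothed_abs_delta(self):
        rng = np.random.default_rng(2)
        st = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.sort(rng.choice(500_000, 200, replace=False)),
                "snp_index_1": rng.random(200),
                "snp_index_2": rng.random(200),
            }
        )
        st["delta_snp_index"] = (st["snp_index_1"] - st["snp_index_2"]).abs()
        out = bsa.delta_windows(st, self.layout)
        ref = bsa.window_smooth(st, "delta_snp_index", self.layout)
        np.testing.assert_allclose(out["value"], ref["value"])

    def test_orders_agree_for_polarized_signal(self):
        # consistently polarized indices: both orders give the same answer
        pos = np.arange(0, 500_000, 2_500)
        st = pd.DataFrame(
            {
                "chrom": "chr1", "pos": pos,
                "snp_index_1": 0.9, "snp_index_2": 0.2,
            }
        )
        st["delta_snp_index"] = 0.7
        a = bsa.delta_windows(st, self.layout, mode="site_delta")
        b = bsa.delta_windows(st, self.layout, mode="window_then_difference")
        np.testing.assert_allclose(a["value"], b["value"])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            bsa.delta_windows(pd.DataFrame(), self.layout, mode="bogus")


class TestIntersections:
    def _regions(self, *ivs):
        return IntervalSet([("chr1", s, e) for s, e in ivs])

    def test_identical_inputs(self):
        r = self._regions((0, 100), (500, 900))
        q = bsa.intersect_methods(r, r)
        assert list(q["methods"].unique()) == ["both"]
        assert bsa.qtl_region_set(q) == r

    def test_disjoint_empty(self):
        q = bsa.intersect_methods(self._regions((0, 100)), self._regions((200, 300)))
        assert q.empty

    def test_population_self_intersection_identity(self):
        q = pd.DataFrame(
            [{"chrom": "chr1", "start": 10, "end": 50, "methods": "both"}]
        )
        out = bsa.intersect_populations(q, q)
        assert [(r.start, r.end) for r in out.itertuples()] == [(10, 50)]

    def test_cross_specific_qtls_vanish(self):
        q1 = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100, "methods": "both"}])
        q2 = pd.DataFrame([{"chrom": "chr2", "start": 0, "end": 100, "methods": "both"}])
        assert bsa.intersect_populations(q1, q2).empty
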