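from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbsdiff import diff_meth as dm
from rrbsdiff import meth_quant as mq

from oracles import fisher_two_sided


def make_wide(records):
    long = pd.DataFrame(records, columns=["chrom", "pos", "sample", "meth",
                                          "total"])
    return mq.to_wide(long)


def levels_frame(chrom_pos_levels, samples):
    idx = pd.MultiIndex.from_tuples(
        [(c, p) for c, p, *_ in chrom_pos_levels], names=["chrom", "pos"])
    data = {s: [row[2 + i] for row in chrom_pos_levels]
            for i, s in enumerate(samples)}
    return pd.DataFrame(data, index=idx)


class TestFisherExact:
    def test_extreme_table(self):
        # margins 10/10, only X=0 and X=10 are as extreme: p = 2 / C(20,10)
        assert dm.fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
            2 / 184756, rel=1e-9)

    def test_balanced_table_p_is_one(self):
        assert dm.fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            r1, r2 = rng.integers(1, 26, size=2)
            a, c = int(rng.integers(0, r1 + 1)), int(rng.integers(0, r2 + 1))
            got = dm.fisher_exact_2x2(a, int(r1) - a, c, int(r2) - c)
            assert got == pytest.approx(
                fisher_two_sided(a, int(r1) - a, c, int(r2) - c), abs=1e-9)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_under_sample_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        assert dm.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            dm.fisher_exact_2x2(c, d, a, b), rel=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            dm.fisher_exact_2x2(0, 0, 3, 4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dm.fisher_exact_2x2(-1, 2, 3, 4)


class TestStrongDmcs:
    def test_exact_one_third_difference_is_not_strong(self):
        """25/30 vs 15/30 differs by exactly 1/3; the strict > gate on the
        printed 33.3% threshold excludes it even though p < 0.05."""
        wide = make_wide([("c1", 5, "A", 25, 30), ("c1", 5, "B", 15, 30)])
        out = dm.call_strong_dmcs(wide, ("A", "B"))
        assert out["p"].iloc[0] < 0.05
        assert not out["is_strong"].iloc[0]

    def test_just_above_one_third_is_strong(self):
        wide = make_wide([("c1", 5, "A", 26, 30), ("c1", 5, "B", 15, 30)])
        out = dm.call_strong_dmcs(wide, ("A", "B"))
        assert out["is_strong"].iloc[0]
        assert out["direction"].iloc[0] == "hyper"

    def test_identical_counts_never_strong(self):
        wide = make_wide([("c1", 5, "A", 12, 30), ("c1", 5, "B", 12, 30)])
        out = dm.call_strong_dmcs(wide, ("A", "B"))
        assert out["delta"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0
        assert not out["is_strong"].iloc[0]

    def test_direction_follows_sign_of_delta(self):
        wide = make_wide([
            ("c1", 1, "A", 28, 30), ("c1", 1, "B", 2, 30),
            ("c1", 2, "A", 2, 30), ("c1", 2, "B", 28, 30),
        ])
        out = dm.call_strong_dmcs(wide, ("A", "B"))
        assert out.loc[out["pos"] == 1, "direction"].iloc[0] == "hyper"
        assert out.loc[out["pos"] == 2, "direction"].iloc[0] == "hypo"
        assert out["is_strong"].all()

    def test_power_and_size_on_planted_sites(self):
        """Coverage-30 Monte Carlo: planted 0.2-vs-0.7 differences are called
        strong >= 90% of the time; null sites exceed p < 0.05 at most 7%."""
        rng = np.random.default_rng(77)
        records = []
        n_null, n_planted = 2000, 200
        for i in range(n_null + n_planted):
            m_a = 0.2
            m_b = 0.7 if i >= n_null else 0.2
            for s, m in (("A", m_a), ("B", m_b)):
                t = max(10, int(rng.poisson(30)))
                records.append(("c1", i, s, int(rng.binomial(t, m)), t))
        wide = make_wide(records)
        out = dm.call_strong_dmcs(wide, ("B", "A"))
        null = out[out["pos"] < n_null]
        planted = out[out["pos"] >= n_null]
        assert (planted["is_strong"].mean()) >= 0.9
        assert (null["p"] < 0.05).mean() <= 0.07

    def test_missing_sample_rejected(self):
        wide = make_wide([("c1", 5, "A", 2, 30)])
        with pytest.raises(KeyError):
            dm.call_strong_dmcs(wide, ("A", "nope"))


def strong_dmc_frame(positions, direction="hyper", chrom="c1"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "level_a": 0.9 if direction == "hyper" else 0.1,
        "level_b": 0.1 if direction == "hyper" else 0.9,
        "delta": 0.8 if direction == "hyper" else -0.8,
        "p": 1e-6, "q": 1e-5, "direction": direction, "is_strong": True,
    })


class TestDmrCalling:
    def test_three_sites_within_gap_form_one_region(self):
        dmcs = strong_dmc_frame([100, 250, 420])
        levels = levels_frame([("c1", 100, 0.2), ("c1", 250, 0.4),
                               ("c1", 420, 0.6)], ["s"])
        out = dm.call_dmrs(dmcs, levels, max_gap=300, min_cpgs=3)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["n_cpgs"]) == (100, 421, 3)
        assert row["level_s"] == pytest.approx(0.4)

    def test_two_sites_below_min_cpgs_no_region(self):
        dmcs = strong_dmc_frame([100, 250])
        levels = levels_frame([("c1", 100, 0.2), ("c1", 250, 0.4)], ["s"])
        assert len(dm.call_dmrs(dmcs, levels)) == 0

    def test_large_gap_splits_chain(self):
        dmcs = strong_dmc_frame([100, 200, 300, 1000, 1100, 1200])
        levels = levels_frame(
            [("c1", p, 0.5) for p in (100, 200, 300, 1000, 1100, 1200)], ["s"])
        out = dm.call_dmrs(dmcs, levels, max_gap=300, min_cpgs=3)
        assert [(r["start"], r["end"]) for _, r in out.iterrows()] == [
            (100, 301), (1000, 1201)]

    def test_opposite_directions_never_chain(self):
        dmcs = pd.concat([strong_dmc_frame([100, 200]),
                          strong_dmc_frame([300], direction="hypo")],
                         ignore_index=True)
        levels = levels_frame([("c1", p, 0.5) for p in (100, 200, 300)], ["s"])
        assert len(dm.call_dmrs(dmcs, levels, min_cpgs=3)) == 0

    def test_region_level_is_in_convex_hull_of_constituents(self, small_gated):
        levels = mq.methylation_levels(small_gated)
        dmcs = dm.call_strong_dmcs(small_gated, ("4F-like", "ESC-like"))
        out = dm.call_dmrs(dmcs, levels)
        assert len(out) > 0
        strong_keys = set(zip(dmcs[dmcs["is_strong"]]["chrom"],
                              dmcs[dmcs["is_strong"]]["pos"]))
        for _, r in out.iterrows():
            positions = [int(p) for p in r["cpg_positions"].split(",")]
            assert all((r["chrom"], p) in strong_keys for p in positions)
            for s in levels.columns:
                vals = [levels.loc[(r["chrom"], p), s] for p in positions]
                assert min(vals) - 1e-12 <= r[f"level_{s}"] <= max(vals) + 1e-12
                assert r[f"level_{s}"] == pytest.approx(np.mean(vals), abs=1e-12)


class TestMergeDmrSets:
    def test_overlapping_intervals_unioned(self):
        a = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["c1"], "start": [150], "end": [250]})
        levels = levels_frame([("c1", 120, 0.1), ("c1", 220, 0.9)], ["s"])
        out = dm.merge_dmr_sets(a, b, levels)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (100, 250)
        assert out["level_s"].iloc[0] == pytest.approx(0.5)

    def test_disjoint_intervals_pass_through(self):
        a = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["c1"], "start": [300], "end": [400]})
        levels = levels_frame([("c1", 150, 0.3), ("c1", 350, 0.7)], ["s"])
        out = dm.merge_dmr_sets(a, b, levels)
        assert [(r["start"], r["end"]) for _, r in out.iterrows()] == [
            (100, 200), (300, 400)]

    def test_touching_intervals_do_not_merge(self):
        a = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["c1"], "start": [200], "end": [300]})
        levels = levels_frame([("c1", 150, 0.3), ("c1", 250, 0.7)], ["s"])
        assert len(dm.merge_dmr_sets(a, b, levels)) == 2

    def test_merged_level_recomputed_from_cpg_table(self):
        """The merged level is the mean over all gated CpGs inside the union,
        not an average of the two parents' levels."""
        a = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["c1"], "start": [50], "end": [200]})
        levels = levels_frame([("c1", 10, 0.1), ("c1", 60, 0.9),
                               ("c1", 150, 0.5), ("c1", 500, 1.0)], ["s"])
        out = dm.merge_dmr_sets(a, b, levels)
        assert len(out) == 1
        assert out["n_cpgs"].iloc[0] == 3
        assert out["level_s"].iloc[0] == pytest.approx((0.1 + 0.9 + 0.5) / 3)


class TestSetComparisonAndVolcano:
    def test_identical_sets(self):
        a = strong_dmc_frame([1, 2, 3])
        cmp = dm.compare_dmc_sets(a, a.copy())
        assert cmp.counts == (3, 0, 0)

    def test_disjoint_sets(self):
        cmp = dm.compare_dmc_sets(strong_dmc_frame([1, 2]),
                                  strong_dmc_frame([3]))
        assert cmp.counts == (0, 2, 1)

    def test_counts_match_set_algebra_oracle(self):
        rng = np.random.default_rng(41)
        pa = sorted(set(rng.integers(0, 200, size=80).tolist()))
        pb = sorted(set(rng.integers(0, 200, size=80).tolist()))
        cmp = dm.compare_dmc_sets(strong_dmc_frame(pa), strong_dmc_frame(pb))
        sa, sb = set(pa), set(pb)
        assert cmp.counts == (len(sa & sb), len(sa - sb), len(sb - sa))
        assert cmp.counts[0] + cmp.counts[1] == len(sa)
        assert cmp.counts[0] + cmp.counts[2] == len(sb)

    def test_volcano_values_and_conservation(self):
        wide = make_wide([
            ("c1", 1, "X", 12, 30), ("c1", 1, "Y", 12, 30),
            ("c1", 2, "X", 30, 30), ("c1", 2, "Y", 0, 30),
        ])
        out = dm.volcano_table([("c1", 1), ("c1", 2), ("c1", 99)], wide,
                               "X", "Y")
        assert len(out) == 2 and out.attrs["n_skipped"] == 1
        row1 = out[out["pos"] == 1].iloc[0]
        assert (row1["delta"], row1["p"]) == (0.0, 1.0)
        row2 = out[out["pos"] == 2].iloc[0]
        assert row2["delta"] == 1.0
        assert row2["p"] == pytest.approx(fisher_two_sided(30, 0, 0, 30),
                                          rel=1e-9)
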