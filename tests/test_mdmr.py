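import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mdmrkit as mk
from mdmrkit.dmrcall import DMRSet
from mdmrkit.mdmr import (
    SupportProfile,
    build_support_profile,
    compute_support_threshold,
    derive_mdmrs,
    select_variable_regions,
    support_curve,
)


def make_dmr_set(sample_id, rows):
    """rows: (chrom, start, end, direction) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    df["n_cpgs"] = 3
    df["mean_beta_case"] = 0.4
    df["mean_beta_control"] = 0.7
    df["delta_beta"] = np.where(df["direction"] == "hyper", 0.3, -0.3)
    df["p_value"] = 0.01
    return DMRSet(sample_id, df)


def brute_force_profile(dmr_sets, universe):
    """Independent oracle: per-locus recount, one unit per sample-direction."""
    rows = []
    for chrom in sorted(universe):
        for pos in universe[chrom]:
            hypo = hyper = 0
            for dset in dmr_sets:
                hit = {"hypo": False, "hyper": False}
                for r in dset.df.itertuples(index=False):
                    if r.chrom == chrom and r.start <= pos < r.end:
                        hit[r.direction] = True
                hypo += hit["hypo"]
                hyper += hit["hyper"]
            rows.append((chrom, pos, hypo, hyper))
    return pd.DataFrame(rows, columns=["chrom", "pos", "hypo_support", "hyper_support"])


def brute_force_mdmrs(profile, threshold, merge_gap):
    """Independent oracle: quadratic chain construction over kept loci."""
    out = []
    for chrom in profile.df["chrom"].unique():
        pos, hypo, hyper = profile.chrom_arrays(chrom)
        for direction, support in (("hypo", hypo), ("hyper", hyper)):
            kept = [(p, s) for p, s in zip(pos, support) if s >= threshold]
            while kept:
                chain = [kept.pop(0)]
                while kept and kept[0][0] - chain[-1][0] <= merge_gap:
                    chain.append(kept.pop(0))
                out.append((chrom, chain[0][0], chain[-1][0] + 1, direction, len(chain)))
    return sorted(out)


class TestSupportProfile:
    universe = {"chr1": np.arange(0, 2000, 100)}

    def test_single_sample_single_dmr(self):
        sets = [make_dmr_set("a", [("chr1", 250, 750, "hypo")])]
        prof = build_support_profile(sets, self.universe)
        assert prof.df["hypo_support"].sum() == 5  # loci 300..700
        assert prof.df["hyper_support"].sum() == 0

    def test_identical_samples_double_support(self):
        rows = [("chr1", 250, 750, "hypo")]
        prof = build_support_profile(
            [make_dmr_set("a", rows), make_dmr_set("b", rows)], self.universe)
        assert prof.df["hypo_support"].max() == 2

    def test_sample_counted_once_per_locus(self):
        """Two abutting DMRs of one sample still contribute one support unit."""
        sets = [make_dmr_set("a", [("chr1", 100, 300, "hypo"),
                                   ("chr1", 300, 500, "hypo")])]
        prof = build_support_profile(sets, self.universe)
        assert prof.df["hypo_support"].max() == 1

    def test_duplicate_sample_id_rejected(self):
        sets = [make_dmr_set("a", [("chr1", 0, 100, "hypo")]),
                make_dmr_set("a", [("chr1", 500, 600, "hypo")])]
        with pytest.raises(ValueError, match="duplicate"):
            build_support_profile(sets, self.universe)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(17)
        universe = {"chr1": np.sort(rng.choice(5000, 80, replace=False)),
                    "chr2": np.sort(rng.choice(5000, 60, replace=False))}
        sets = []
        for i in range(20):
            rows = []
            for _ in range(rng.integers(1, 6)):
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                s = int(rng.integers(0, 4500))
                rows.append((chrom, s, s + int(rng.integers(50, 400)),
                             "hypo" if rng.random() < 0.5 else "hyper"))
            rows.sort()
            merged = [rows[0]]
            for r in rows[1:]:  # drop overlaps within a sample
                if r[0] != merged[-1][0] or r[1] >= merged[-1][2]:
                    merged.append(r)
            sets.append(make_dmr_set(f"s{i}", merged))
        prof = build_support_profile(sets, universe)
        expected = brute_force_profile(sets, universe)
        pd.testing.assert_frame_equal(
            prof.df.reset_index(drop=True).astype({"hypo_support": int, "hyper_support": int}),
            expected.astype({"pos": prof.df["pos"].dtype}),
            check_dtype=False)


class TestSupportThreshold:
    @pytest.mark.parametrize("n,frac,expected", [
        (31, 0.70, 22),   # the printed cohort cutoff: 70% of 31 samples
        (10, 0.70, 7),
        (20, 0.70, 14),
        (12, 0.70, 9),
        (3, 1.0, 3),
    ])
    def test_values(self, n, frac, expected):
        assert compute_support_threshold(n, frac) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_support_threshold(0, 0.7)
        with pytest.raises(ValueError):
            compute_support_threshold(10, 0.0)

    @given(st.integers(1, 500), st.floats(0.01, 1.0))
    def test_is_ceiling(self, n, frac):
        t = compute_support_threshold(n, frac)
        assert t >= 1
        assert (t - 1) < frac * n + 1e-6
        assert t >= frac * n - 1e-6


def profile_from_arrays(pos, hypo, hyper=None, n_samples=10):
    df = pd.DataFrame({"chrom": "chr1", "pos": np.asarray(pos),
                       "hypo_support": np.asarray(hypo),
                       "hyper_support": np.zeros(len(pos), int) if hyper is None else np.asarray(hyper)})
    return SupportProfile(df, n_samples)


class TestDeriveMdmrs:
    def test_gap_rule_splits_regions(self):
        """Kept loci at 100, 400, 1200: the 800 bp step exceeds the 500 bp
        merge rule, forcing [100,401) and [1200,1201)."""
        prof = profile_from_arrays([100, 400, 1200], [5, 5, 5])
        out = derive_mdmrs(prof, threshold=5)
        got = list(zip(out["start"], out["end"]))
        assert got == [(100, 401), (1200, 1201)]

    def test_no_locus_reaches_threshold(self):
        prof = profile_from_arrays([100, 200], [3, 4])
        assert len(derive_mdmrs(prof, threshold=5)) == 0

    def test_transitive_chaining_spans_far(self):
        pos = np.arange(0, 5000, 400)  # every step < 500 -> one chain
        prof = profile_from_arrays(pos, np.full(len(pos), 5))
        out = derive_mdmrs(prof, threshold=5)
        assert len(out) == 1
        assert out.iloc[0]["width_bp"] > 4000

    def test_directions_independent(self):
        prof = profile_from_arrays([100, 200], [5, 0], [0, 5])
        out = derive_mdmrs(prof, threshold=5)
        assert set(out["direction"]) == {"hypo", "hyper"}
        assert len(out) == 2

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            pos = np.sort(rng.choice(20_000, n, replace=False))
            prof = profile_from_arrays(pos, rng.integers(0, 8, n), rng.integers(0, 8, n))
            thr = int(rng.integers(1, 8))
            gap = int(rng.choice([100, 500, 1000]))
            got = derive_mdmrs(prof, thr, gap)
            got_list = sorted(zip(got["chrom"], got["start"], got["end"],
                                  got["direction"], got["n_cpgs"]))
            assert got_list == brute_force_mdmrs(prof, thr, gap)


class TestSupportCurve:
    def test_single_sample_curve(self):
        prof = profile_from_arrays([100, 200, 1200], [1, 1, 1], n_samples=3)
        curve = support_curve(prof)
        assert curve.loc[curve["threshold"] == 1, "n_hypo_mdmrs"].iloc[0] == 2
        assert (curve.loc[curve["threshold"] >= 2, "n_hypo_mdmrs"] == 0).all()

    def test_kept_cpg_counts_non_increasing(self):
        rng = np.random.default_rng(31)
        pos = np.sort(rng.choice(50_000, 200, replace=False))
        prof = profile_from_arrays(pos, rng.integers(0, 10, 200),
                                   rng.integers(0, 10, 200), n_samples=10)
        curve = support_curve(prof)
        assert (np.diff(curve["n_hypo_cpgs"]) <= 0).all()
        assert (np.diff(curve["n_hyper_cpgs"]) <= 0).all()

    def test_planted_cohort_curve_hits_truth(self, small_cohort, small_cohort_dmrs):
        """With every tumor carrying all 20 planted regions per direction,
        the curve counts exactly 20 per direction across the whole mid range
        of thresholds (per-sample CpG dropout erodes it only near N = 12)."""
        cfg, tracks, truth = small_cohort
        prof = build_support_profile(small_cohort_dmrs, truth.grid.universe())
        curve = support_curve(prof).set_index("threshold")
        for n in range(2, 11):
            assert curve.loc[n, "n_hypo_mdmrs"] == 20
            assert curve.loc[n, "n_hyper_mdmrs"] == 20
        assert curve.loc[12, "n_hypo_mdmrs"] >= 15


class TestSelectVariableRegions:
    def test_single_variable_region_selected_first(self):
        values = pd.DataFrame(
            {"s1": [0.1, 0.5, 0.5], "s2": [0.9, 0.5, 0.5]},
            index=["r1", "r2", "r3"])
        sel = select_variable_regions(values, top_fraction=0.3)
        assert list(sel) == ["r1"]

    def test_top_fraction_count(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.random((1000, 5)),
                              index=[f"r{i}" for i in range(1000)])
        sel = select_variable_regions(values, top_fraction=0.025)
        assert len(sel) == 25

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.random((200, 8)),
                              index=[f"r{i}" for i in range(200)])
        sel = select_variable_regions(values, top_fraction=0.1)
        var = values.var(axis=1, ddof=1)
        expected = set(var.sort_values(ascending=False).index[:20])
        assert set(sel) == expected

    def test_all_constant_warns_empty(self):
        values = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            sel = select_variable_regions(values)
        assert len(sel) == 0


def test_mdmr_recovery_jaccard(small_cohort, small_cohort_dmrs):
    """Consensus regions at the 70% threshold recover the planted truth with
    base-level Jaccard >= 0.8 per direction."""
    cfg, tracks, truth = small_cohort
    prof = build_support_profile(small_cohort_dmrs, truth.grid.universe())
    thr = compute_support_threshold(len(small_cohort_dmrs), 0.70)
    out = derive_mdmrs(prof, thr)
    for direction in ("hypo", "hyper"):
        got = out[out["direction"] == direction]
        want = truth.regions_frame(direction)
        assert mk.interval_jaccard(got, want) >= 0.8
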