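import dataclasses

import numpy as np
import pytest

import mdmrkit as mk
from mdmrkit.methio import GenomicRegion, region_mean_beta
from mdmrkit.simcohort import (
    PlantedDomain,
    PlantedRegion,
    SimulationConfig,
    simulate_background_track,
)


def _tiny_config(**kw):
    base = dict(seed=2, n_chromosomes=2, n_cpgs_per_chrom=1500,
                n_tumor_samples=3, n_normal_samples=2,
                n_islands_per_chrom=10, island_cpg_fraction=0.3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            _tiny_config(baseline_beta_open_sea=1.5)

    def test_positive_counts(self):
        with pytest.raises(ValueError):
            _tiny_config(n_tumor_samples=0)

    def test_overlapping_planted_regions_rejected(self):
        regs = (
            PlantedRegion("chr1", 100, 500, "hypo", 0.7, 0.4),
            PlantedRegion("chr1", 400, 800, "hypo", 0.7, 0.4),
        )
        with pytest.raises(ValueError, match="overlap"):
            _tiny_config(planted_shared_regions=regs)

    def test_region_without_cpgs_rejected(self):
        cfg = _tiny_config(planted_shared_regions=(
            PlantedRegion("chr2", 0, 2, "hypo", 0.7, 0.4),))
        with pytest.raises(ValueError, match="no CpGs"):
            mk.simulate_cohort(cfg)

    def test_small_effect_rejected(self):
        with pytest.raises(ValueError, match="0.15"):
            PlantedRegion("chr1", 0, 100, "hypo", 0.5, 0.45)

    def test_direction_sign_consistency(self):
        with pytest.raises(ValueError, match="direction"):
            PlantedRegion("chr1", 0, 100, "hyper", 0.7, 0.4)

    def test_domain_class_beta_consistency(self):
        with pytest.raises(ValueError):
            PlantedDomain("chr1", 0, 2_000_000, 0.5, "desert")
        with pytest.raises(ValueError):
            PlantedDomain("chr1", 0, 2_000_000, 0.1, "pmd")


class TestSimulateCohort:
    def test_no_signal_genomewide_mean(self):
        cfg = _tiny_config(baseline_beta_open_sea=0.75, baseline_beta_island=0.75)
        tracks, _ = mk.simulate_cohort(cfg)
        for t in tracks:
            assert np.nanmean(t.betas()) == pytest.approx(0.75, abs=0.02)

    def test_planted_hypo_region_betas(self):
        """Carrier tumors sit near beta 0.406 inside a planted hypomethylated
        region whose normal level is 0.732."""
        cfg = _tiny_config()
        grid = mk.cpg_grid(cfg)
        regs = mk.design_shared_regions(grid, 1, 0, betas_hypo=(0.732, 0.406), seed=2)
        cfg = dataclasses.replace(cfg, planted_shared_regions=regs)
        tracks, truth = mk.simulate_cohort(cfg)
        region = GenomicRegion(regs[0].chrom, regs[0].start, regs[0].end)
        sheet = truth.sample_sheet.set_index("sample_id")
        for t in tracks:
            mean = region_mean_beta(t, region)
            if sheet.loc[t.sample_id, "role"] == "tumor":
                assert mean == pytest.approx(0.406, abs=0.05)
            else:
                assert mean == pytest.approx(0.732, abs=0.05)

    def test_seed_determinism(self):
        cfg = _tiny_config()
        t1, _ = mk.simulate_cohort(cfg)
        t2, _ = mk.simulate_cohort(cfg)
        for a, b in zip(t1, t2):
            assert a.df.equals(b.df)

    def test_different_seed_differs(self):
        t1, _ = mk.simulate_cohort(_tiny_config(seed=2))
        t2, _ = mk.simulate_cohort(_tiny_config(seed=3))
        assert not t1[0].df.equals(t2[0].df)

    def test_shared_grid_across_samples(self):
        tracks, _ = mk.simulate_cohort(_tiny_config())
        ref = tracks[0]
        for t in tracks[1:]:
            for chrom in ref.chroms:
                assert np.array_equal(t.positions(chrom), ref.positions(chrom))

    def test_every_sample_has_truth_record(self):
        tracks, truth = mk.simulate_cohort(_tiny_config())
        assert set(truth.sample_sheet["sample_id"]) == {t.sample_id for t in tracks}

    def test_carrier_fraction_partial(self):
        cfg = _tiny_config(n_tumor_samples=10, n_normal_samples=0)
        grid = mk.cpg_grid(cfg)
        regs = mk.design_shared_regions(grid, 2, 0, carrier_fraction=0.5, seed=7)
        cfg = dataclasses.replace(cfg, planted_shared_regions=regs)
        _, truth = mk.simulate_cohort(cfg)
        for carriers in truth.carriers.values():
            assert len(carriers) == 5

    def test_domain_lowers_tumor_betas(self):
        cfg = _tiny_config(
            n_chromosomes=1, chrom_length_bp=4_000_000, n_cpgs_per_chrom=8000,
            desert_spec=(PlantedDomain("chr1", 1_000_000, 2_500_000, 0.1, "desert"),))
        tracks, truth = mk.simulate_cohort(cfg)
        region = GenomicRegion("chr1", 1_000_000, 2_500_000)
        sheet = truth.sample_sheet.set_index("sample_id")
        for t in tracks:
            mean = region_mean_beta(t, region)
            if sheet.loc[t.sample_id, "role"] == "tumor":
                assert mean == pytest.approx(0.1, abs=0.03)
            else:
                assert mean > 0.4  # normals keep the mixed island/open-sea baseline


class TestSimulateCfdna:
    @pytest.fixture(scope="class")
    @staticmethod
    def pair():
        cfg = _tiny_config(n_tumor_samples=1, n_normal_samples=1)
        grid = mk.cpg_grid(cfg)
        regs = mk.design_shared_regions(grid, 2, 2, seed=5)
        cfg = dataclasses.replace(cfg, planted_shared_regions=regs)
        tracks, truth = mk.simulate_cohort(cfg)
        bg = simulate_background_track(cfg, "BG", seed=77)
        return cfg, tracks[0], bg, truth

    def test_fraction_zero_matches_background(self, pair):
        cfg, tumor, bg, truth = pair
        cf = mk.simulate_cfdna(tumor, bg, 0.0, seed=1)
        for reg in truth.shared_regions:
            region = GenomicRegion(reg.chrom, reg.start, reg.end)
            d = region_mean_beta(cf, region) - region_mean_beta(bg, region)
            assert abs(d) < 0.05

    def test_fraction_one_matches_tumor(self, pair):
        cfg, tumor, bg, truth = pair
        cf = mk.simulate_cfdna(tumor, bg, 1.0, hyper_attenuation=0.0, seed=2)
        for direction in ("hypo", "hyper"):
            regs = [r for r in truth.shared_regions if r.direction == direction]
            diffs = [
                region_mean_beta(cf, GenomicRegion(r.chrom, r.start, r.end))
                - region_mean_beta(tumor, GenomicRegion(r.chrom, r.start, r.end))
                for r in regs
            ]
            assert abs(np.mean(diffs)) < 0.05

    def test_mixture_closed_form(self, pair):
        """f=0.3 over a 0.732->0.406 hypo region gives 0.3*0.406+0.7*0.732=0.634."""
        cfg, tumor, bg, truth = pair
        cf = mk.simulate_cfdna(tumor, bg, 0.3, seed=3)
        hypo = [r for r in truth.shared_regions if r.direction == "hypo"]
        means = [region_mean_beta(cf, GenomicRegion(r.chrom, r.start, r.end))
                 for r in hypo]
        assert np.mean(means) == pytest.approx(0.3 * 0.406 + 0.7 * 0.732, abs=0.05)

    def test_mixture_linearity(self, pair):
        cfg, tumor, bg, truth = pair
        reg = truth.shared_regions[0]
        region = GenomicRegion(reg.chrom, reg.start, reg.end)
        bt = region_mean_beta(tumor, region)
        bb = region_mean_beta(bg, region)
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            cf = mk.simulate_cfdna(tumor, bg, f, seed=int(f * 100))
            assert region_mean_beta(cf, region) == pytest.approx(
                f * bt + (1 - f) * bb, abs=0.06)

    def test_hyper_attenuation_suppresses_hyper_signal(self, pair):
        cfg, tumor, bg, truth = pair
        hyper = [r for r in truth.shared_regions if r.direction == "hyper"]
        cf_full = mk.simulate_cfdna(tumor, bg, 0.5, hyper_attenuation=0.0,
                                    seed=4, hyper_regions=hyper)
        cf_att = mk.simulate_cfdna(tumor, bg, 0.5, hyper_attenuation=1.0,
                                   seed=4, hyper_regions=hyper)
        for r in hyper:
            region = GenomicRegion(r.chrom, r.start, r.end)
            assert region_mean_beta(cf_att, region) < region_mean_beta(cf_full, region)

    def test_mismatched_grids_rejected(self, pair):
        cfg, tumor, bg, _ = pair
        other, _ = mk.simulate_cohort(_tiny_config(seed=99, n_cpgs_per_chrom=1400))
        with pytest.raises(ValueError):
            mk.simulate_cfdna(tumor, other[0], 0.5, seed=0)

    def test_bad_fraction_rejected(self, pair):
        cfg, tumor, bg, _ = pair
        with pytest.raises(ValueError):
            mk.simulate_cfdna(tumor, bg, 1.5, seed=0)


def test_coverage_conservation():
    """methylated + unmethylated counts reproduce the drawn coverage exactly
    (the generator never loses reads)."""
    tracks, _ = mk.simulate_cohort(_tiny_config())
    for t in tracks:
        cov = t.coverage()
        assert (cov == t.df["n_meth"] + t.df["n_unmeth"]).all()
        assert (cov >= 0).all()


def test_design_regions_respect_separation():
    cfg = _tiny_config()
    grid = mk.cpg_grid(cfg)
    regs = mk.design_shared_regions(grid, 6, 6, seed=1, min_separation_bp=5000)
    by_chrom = {}
    for r in regs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 - e1 >= 5000
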