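import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mdmrkit as mk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_track(sample_id, chrom_pos, betas, coverage=30, seed=0):
    """Deterministic toy track: exact counts round(beta*coverage) per CpG.

    ``chrom_pos``: dict chrom -> position array; ``betas``: matching dict
    (or scalar).  No sampling noise — counts are the rounded expectation.
    """
    frames = []
    for chrom, pos in chrom_pos.items():
        pos = np.asarray(pos)
        b = betas[chrom] if isinstance(betas, dict) else np.full(len(pos), betas)
        n_meth = np.round(np.asarray(b) * coverage).astype(int)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "n_meth": n_meth,
            "n_unmeth": coverage - n_meth,
        }))
    return mk.MethylomeTrack(sample_id, pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def small_cohort():
    """12 tumor / 12 matched-normal cohort with 20 planted regions per
    direction at the hypo 0.732->0.406 and hyper 0.308->0.643 beta levels."""
    cfg = mk.SimulationConfig(
        seed=3, n_chromosomes=2, n_cpgs_per_chrom=6000,
        n_tumor_samples=12, n_normal_samples=12,
        n_islands_per_chrom=30, island_cpg_fraction=0.25,
    )
    grid = mk.cpg_grid(cfg)
    regions = mk.design_shared_regions(grid, 20, 20, seed=3)
    cfg = dataclasses.replace(cfg, planted_shared_regions=regions)
    tracks, truth = mk.simulate_cohort(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def small_cohort_dmrs(small_cohort):
    """Per-tumor DMR sets for the small cohort (matched-normal comparators)."""
    cfg, tracks, truth = small_cohort
    by_id = {t.sample_id: t for t in tracks}
    plan = mk.plan_comparators(truth.sample_sheet)
    sets = [mk.call_dmrs(by_id[t], [by_id[c] for c in ctl], sample_id=t)
            for t, ctl in plan.items()]
    return sets
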