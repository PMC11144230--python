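"""Synthetic multi-sample WGBS-like cohort generator.

Emulates the structure of a tumor / matched-normal / plasma methylation
cohort: a shared CpG grid (clustered islands plus open-sea background),
regionally assigned mean beta values, beta-binomial read counts around
those means with negative-binomial coverage, planted shared and private
differentially methylated regions, megabase-scale hypomethylated domains
(PMDs and methylation deserts), and cell-free DNA built as tumor/leukocyte
mixtures.  Ground truth for every planted feature is returned alongside the
tracks, so every downstream stage is testable without external data.

Defaults mirror a pediatric pan-cancer study design: 31 tumors, 13 matched
normals across 11 diagnoses, hypomethylated events moving beta from ~0.73
(normal) to ~0.41 (tumor) and hypermethylated events from ~0.31 to ~0.64,
mean coverage 30x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methio import MethylomeTrack

#: diagnosis codes cycled over tumor samples (11 pediatric solid tumor types)
DIAGNOSES = ("NBL", "OS", "FHC", "HB", "AE", "DSRCT", "MRT", "HL", "ERMS", "TER", "WT")


@dataclass(frozen=True)
class PlantedRegion:
    """A ground-truth differentially methylated region.

    Coordinates are 0-based half-open.  ``carrier_fraction`` is the fraction
    of tumor samples carrying the event; non-carriers (and all normals) sit
    at ``beta_normal``.
    """

    chrom: str
    start: int
    end: int
    direction: str  # "hyper" | "hypo"
    beta_normal: float
    beta_tumor: float
    carrier_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("planted region start must be < end")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")
        delta = self.beta_tumor - self.beta_normal
        if abs(delta) < 0.15:
            raise ValueError("planted DMR effect |beta_tumor - beta_normal| must be >= 0.15")
        if (delta > 0) != (self.direction == "hyper"):
            raise ValueError("direction inconsistent with sign of beta_tumor - beta_normal")
        for b in (self.beta_normal, self.beta_tumor):
            if not 0.0 <= b <= 1.0:
                raise ValueError("betas must lie in [0, 1]")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")

    @property
    def delta_beta(self) -> float:
        return self.beta_tumor - self.beta_normal


@dataclass(frozen=True)
class PlantedDomain:
    """A ground-truth megabase-scale hypomethylated domain."""

    chrom: str
    start: int
    end: int
    target_mean_beta: float
    klass: str  # "pmd" | "desert"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("domain start must be < end")
        if self.klass == "desert":
            if not self.target_mean_beta < 0.2:
                raise ValueError("desert requires target_mean_beta < 0.2")
        elif self.klass == "pmd":
            if not 0.2 <= self.target_mean_beta < 0.7:
                raise ValueError("pmd requires 0.2 <= target_mean_beta < 0.7")
        else:
            raise ValueError(f"bad domain class {self.klass!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator.

    ``beta_precision`` is the beta-binomial concentration: per-CpG latent
    methylation proportions are drawn from Beta(beta*c, (1-beta)*c), so
    larger values mean less between-read-bundle overdispersion.  Coverage is
    negative-binomial with the given mean and dispersion (variance =
    mean + mean^2 / dispersion).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 3_000_000
    n_cpgs_per_chrom: int = 6_000
    n_tumor_samples: int = 31
    n_normal_samples: int = 13
    mean_coverage: float = 30.0
    coverage_dispersion: float = 10.0
    beta_precision: float = 100.0
    baseline_beta_open_sea: float = 0.75
    baseline_beta_island: float = 0.15
    n_islands_per_chrom: int = 20
    island_width_bp: int = 1_000
    island_cpg_fraction: float = 0.2
    planted_shared_regions: tuple[PlantedRegion, ...] = ()
    planted_private_region_rate: float = 0.0
    pmd_spec: tuple[PlantedDomain, ...] = ()
    desert_spec: tuple[PlantedDomain, ...] = ()
    cfdna_tumor_fraction: float = 0.1
    cfdna_hyper_attenuation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_cpgs_per_chrom",
                     "n_tumor_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_normal_samples < 0:
            raise ValueError("n_normal_samples must be >= 0")
        for name in ("mean_coverage", "coverage_dispersion", "beta_precision"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("baseline_beta_open_sea", "baseline_beta_island",
                     "island_cpg_fraction", "cfdna_tumor_fraction",
                     "cfdna_hyper_attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.planted_private_region_rate < 0:
            raise ValueError("planted_private_region_rate must be >= 0")
        self._check_planted()

    def _check_planted(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        valid = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for reg in self.planted_shared_regions:
            if reg.chrom not in valid:
                raise ValueError(f"planted region on unknown chromosome {reg.chrom}")
            if reg.end > self.chrom_length_bp or reg.start < 0:
                raise ValueError("planted region outside chromosome bounds")
            by_chrom.setdefault(reg.chrom, []).append((reg.start, reg.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("planted shared regions overlap")
        for dom in (*self.pmd_spec, *self.desert_spec):
            if dom.chrom not in valid or dom.end > self.chrom_length_bp or dom.start < 0:
                raise ValueError("planted domain outside chromosome bounds")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class CpGGrid:
    """Shared CpG coordinate system of a simulated cohort."""

    positions: dict[str, np.ndarray]
    island_mask: dict[str, np.ndarray]
    islands: pd.DataFrame  # chrom, start, end

    @property
    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def universe(self) -> dict[str, np.ndarray]:
        return {c: p.copy() for c, p in self.positions.items()}

    def cpg_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return np.arange(lo, hi)


@dataclass
class SimTruth:
    """Ground-truth record accompanying a simulated cohort."""

    sample_sheet: pd.DataFrame  # sample_id, patient_id, diagnosis, role
    shared_regions: tuple[PlantedRegion, ...]
    carriers: dict[int, tuple[str, ...]]  # region index -> carrier tumor sample ids
    private_regions: dict[str, tuple[PlantedRegion, ...]]
    domains: tuple[PlantedDomain, ...]
    grid: CpGGrid
    cfdna_fractions: dict[str, float] = field(default_factory=dict)

    def regions_frame(self, direction: str | None = None) -> pd.DataFrame:
        rows = [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "direction": r.direction, "beta_normal": r.beta_normal,
             "beta_tumor": r.beta_tumor, "carrier_fraction": r.carrier_fraction}
            for r in self.shared_regions
            if direction is None or r.direction == direction
        ]
        cols = ["chrom", "start", "end", "direction", "beta_normal",
                "beta_tumor", "carrier_fraction"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# grid and region design


def cpg_grid(config: SimulationConfig) -> CpGGrid:
    """Deterministic CpG placement for a config (depends only on the seed).

    A fixed fraction of CpGs is packed into dense island runs at random
    loci; the rest are scattered uniformly (open sea).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC9]))
    positions: dict[str, np.ndarray] = {}
    island_mask: dict[str, np.ndarray] = {}
    island_rows = []
    n_island_cpgs_total = int(round(config.island_cpg_fraction * config.n_cpgs_per_chrom))
    n_isl = max(1, config.n_islands_per_chrom)
    per_island = max(2, n_island_cpgs_total // n_isl)
    for chrom in config.chrom_names:
        margin = config.island_width_bp + 10
        centers = np.sort(rng.integers(margin, config.chrom_length_bp - margin, n_isl))
        isl_pos = []
        for c in centers:
            spacing = max(2, config.island_width_bp // per_island)
            run = c + spacing * np.arange(per_island)
            isl_pos.append(run)
            island_rows.append({"chrom": chrom, "start": int(run[0]), "end": int(run[-1]) + 2})
        isl_pos = np.concatenate(isl_pos)
        n_open = max(0, config.n_cpgs_per_chrom - len(isl_pos))
        open_pos = rng.choice(config.chrom_length_bp, size=n_open, replace=False)
        pos = np.concatenate([isl_pos, open_pos])
        mask = np.concatenate([np.ones(len(isl_pos), bool), np.zeros(n_open, bool)])
        order = np.argsort(pos, kind="stable")
        pos, mask = pos[order], mask[order]
        pos, uniq_idx = np.unique(pos, return_index=True)
        positions[chrom] = pos.astype(np.int64)
        island_mask[chrom] = mask[uniq_idx]
    return CpGGrid(positions, island_mask, pd.DataFrame(island_rows))


def design_shared_regions(
    grid: CpGGrid,
    n_hypo: int,
    n_hyper: int,
    *,
    betas_hypo: tuple[float, float] = (0.732, 0.406),
    betas_hyper: tuple[float, float] = (0.308, 0.643),
    cpgs_per_region: int = 15,
    carrier_fraction: float = 1.0,
    max_intra_gap_bp: int = 100,
    min_separation_bp: int = 5_000,
    seed: int = 0,
) -> tuple[PlantedRegion, ...]:
    """Place non-overlapping shared regions snapped to dense CpG runs.

    Regions span exactly ``cpgs_per_region`` consecutive grid CpGs (start =
    first CpG, end = last CpG + 1) whose internal gaps are all within
    ``max_intra_gap_bp`` — DMR-like events sit in CpG-dense sequence, which
    in this grid means island runs.  Chosen runs are separated by at least
    ``min_separation_bp`` so downstream merging can never bridge two
    planted regions, and directions are assigned at random.  ``betas_*``
    are (normal, tumor) mean beta levels.
    """
    rng = np.random.default_rng(seed)
    total = n_hypo + n_hyper
    slots: list[tuple[str, int]] = []  # (chrom, start CpG index)
    k = cpgs_per_region - 1
    for chrom, pos in grid.positions.items():
        if len(pos) <= k:
            continue
        ok = (np.diff(pos) <= max_intra_gap_bp).astype(int)
        dense = np.convolve(ok, np.ones(k, dtype=int), "valid") == k
        last_end = -min_separation_bp
        for i in np.flatnonzero(dense):
            start, end = int(pos[i]), int(pos[i + k]) + 1
            if start - last_end >= min_separation_bp:
                slots.append((chrom, int(i)))
                last_end = end
    if len(slots) < total:
        raise ValueError(
            f"grid has only {len(slots)} dense CpG runs for {total} planted regions; "
            "increase island count/size or relax max_intra_gap_bp")
    chosen = [slots[i] for i in rng.choice(len(slots), size=total, replace=False)]
    directions = np.array(["hypo"] * n_hypo + ["hyper"] * n_hyper)
    rng.shuffle(directions)
    regions = []
    for (chrom, i0), direction in zip(sorted(chosen), directions):
        pos = grid.positions[chrom]
        start = int(pos[i0])
        end = int(pos[i0 + k]) + 1
        bn, bt = betas_hypo if direction == "hypo" else betas_hyper
        regions.append(PlantedRegion(chrom, start, end, str(direction), bn, bt, carrier_fraction))
    return tuple(regions)


# ---------------------------------------------------------------------------
# simulation


def _draw_counts(mean_beta: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial coverage and beta-binomial methylated counts."""
    m, d = config.mean_coverage, config.coverage_dispersion
    cov = rng.negative_binomial(d, d / (d + m), size=mean_beta.shape)
    b = np.clip(mean_beta, 1e-4, 1 - 1e-4)
    c = config.beta_precision
    p = rng.beta(b * c, (1 - b) * c)
    n_meth = rng.binomial(cov, p)
    return n_meth, cov - n_meth


def _baseline_betas(grid: CpGGrid, config: SimulationConfig) -> dict[str, np.ndarray]:
    out = {}
    for chrom, pos in grid.positions.items():
        b = np.full(len(pos), config.baseline_beta_open_sea)
        b[grid.island_mask[chrom]] = config.baseline_beta_island
        out[chrom] = b
    return out


def _apply_regions(betas: dict[str, np.ndarray], grid: CpGGrid,
                   regions, attr: str) -> None:
    for reg in regions:
        idx = grid.cpg_indices(reg.chrom, reg.start, reg.end)
        betas[reg.chrom][idx] = getattr(reg, attr)


def _track_from_means(sample_id: str, betas: dict[str, np.ndarray],
                      grid: CpGGrid, config: SimulationConfig,
                      rng: np.random.Generator) -> MethylomeTrack:
    frames = []
    for chrom in grid.positions:
        n_meth, n_unmeth = _draw_counts(betas[chrom], config, rng)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": grid.positions[chrom],
            "n_meth": n_meth, "n_unmeth": n_unmeth,
        }))
    df = pd.concat(frames, ignore_index=True)
    return MethylomeTrack(sample_id, df, validate=False)


def _sample_private_regions(grid: CpGGrid, config: SimulationConfig,
                            forbidden: list[tuple[str, int, int]],
                            rng: np.random.Generator) -> tuple[PlantedRegion, ...]:
    n = rng.poisson(config.planted_private_region_rate)
    out: list[PlantedRegion] = []
    chroms = list(grid.positions)
    attempts = 0
    while len(out) < n and attempts < 50 * (n + 1):
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        pos = grid.positions[chrom]
        width = int(rng.integers(8, 16))
        if len(pos) <= width:
            continue
        i0 = int(rng.integers(0, len(pos) - width))
        start, end = int(pos[i0]), int(pos[i0 + width - 1]) + 1
        if any(c == chrom and s < end and start < e for c, s, e in forbidden):
            continue
        base = config.baseline_beta_open_sea
        if rng.random() < 0.5:
            bt = max(0.02, base - 0.3)
            direction = "hypo"
        else:
            bt = min(0.98, base + 0.2)
            direction = "hyper" if bt > base else "hypo"
        if abs(bt - base) < 0.15:
            continue
        out.append(PlantedRegion(chrom, start, end, direction, base, bt, 1.0))
        forbidden.append((chrom, start, end))
    return tuple(out)


def build_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Tumor/normal sample sheet with patient pairing and cycled diagnoses.

    The first ``n_normal_samples`` tumors get a matched normal from the same
    patient; the remainder are unpaired (exercising pooled-normal
    comparators downstream).
    """
    rows = []
    for i in range(config.n_tumor_samples):
        patient = f"P{i:03d}"
        dx = DIAGNOSES[i % len(DIAGNOSES)]
        rows.append({"sample_id": f"T{i:03d}", "patient_id": patient,
                     "diagnosis": dx, "role": "tumor"})
        if i < config.n_normal_samples:
            rows.append({"sample_id": f"N{i:03d}", "patient_id": patient,
                         "diagnosis": dx, "role": "normal"})
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "diagnosis", "role"])


def simulate_cohort(config: SimulationConfig) -> tuple[list[MethylomeTrack], SimTruth]:
    """Simulate all tissue tracks of a cohort plus its ground truth.

    CpG positions are identical across samples.  Carriers of a planted
    shared region sit at ``beta_tumor`` inside it, all other samples at
    ``beta_normal``; domains lower tumor betas to their target level
    (shared/private regions take precedence over domains).  Deterministic
    given ``config.seed``.
    """
    grid = cpg_grid(config)
    for reg in config.planted_shared_regions:
        if len(grid.cpg_indices(reg.chrom, reg.start, reg.end)) == 0:
            raise ValueError(f"planted region {reg.chrom}:{reg.start}-{reg.end} contains no CpGs")
    sheet = build_sample_sheet(config)
    ss = np.random.SeedSequence([config.seed, 0x5A])
    n_samples = len(sheet)
    children = ss.spawn(n_samples + 2)
    plan_rng = np.random.default_rng(children[0])

    tumor_ids = sheet.loc[sheet["role"] == "tumor", "sample_id"].tolist()
    carriers: dict[int, tuple[str, ...]] = {}
    for ri, reg in enumerate(config.planted_shared_regions):
        k = int(round(reg.carrier_fraction * len(tumor_ids)))
        idx = plan_rng.choice(len(tumor_ids), size=k, replace=False)
        carriers[ri] = tuple(tumor_ids[j] for j in sorted(idx))

    forbidden = [(r.chrom, r.start, r.end) for r in config.planted_shared_regions]
    domains = (*config.desert_spec, *config.pmd_spec)
    private: dict[str, tuple[PlantedRegion, ...]] = {}
    priv_rng = np.random.default_rng(children[1])
    if config.planted_private_region_rate > 0:
        for sid in tumor_ids:
            private[sid] = _sample_private_regions(grid, config, forbidden, priv_rng)

    base = _baseline_betas(grid, config)
    tracks: list[MethylomeTrack] = []
    for k, row in enumerate(sheet.itertuples(index=False)):
        betas = {c: b.copy() for c, b in base.items()}
        if row.role == "tumor":
            for dom in domains:
                idx = grid.cpg_indices(dom.chrom, dom.start, dom.end)
                betas[dom.chrom][idx] = dom.target_mean_beta
        # everyone sits at beta_normal in planted regions ...
        _apply_regions(betas, grid, config.planted_shared_regions, "beta_normal")
        if row.role == "tumor":
            # ... except carrier tumors, which flip to beta_tumor
            for ri, reg in enumerate(config.planted_shared_regions):
                if row.sample_id in carriers[ri]:
                    idx = grid.cpg_indices(reg.chrom, reg.start, reg.end)
                    betas[reg.chrom][idx] = reg.beta_tumor
            _apply_regions(betas, grid, private.get(row.sample_id, ()), "beta_tumor")
        rng = np.random.default_rng(children[k + 2])
        tracks.append(_track_from_means(row.sample_id, betas, grid, config, rng))

    truth = SimTruth(sheet, config.planted_shared_regions, carriers,
                     private, domains, grid)
    return tracks, truth


def simulate_background_track(config: SimulationConfig, sample_id: str = "BG",
                              seed: int | None = None) -> MethylomeTrack:
    """A leukocyte-like background methylome: baseline betas with
    ``beta_normal`` inside planted regions (no tumor events)."""
    grid = cpg_grid(config)
    betas = _baseline_betas(grid, config)
    _apply_regions(betas, grid, config.planted_shared_regions, "beta_normal")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed if seed is None else seed, 0xBB]))
    return _track_from_means(sample_id, betas, grid, config, rng)


def simulate_cfdna(
    tumor: MethylomeTrack,
    background: MethylomeTrack,
    tumor_fraction: float,
    hyper_attenuation: float = 0.0,
    seed: int = 0,
    *,
    hyper_regions=(),
    mean_coverage: float = 30.0,
    coverage_dispersion: float = 10.0,
    beta_precision: float = 100.0,
    sample_id: str | None = None,
) -> MethylomeTrack:
    """Mix a tumor and a background track into a cell-free DNA track.

    Per CpG the expected beta is ``f * b_tumor + (1 - f) * b_background``
    with ``f = tumor_fraction``; inside ``hyper_regions`` (tumor-
    hypermethylated planted regions) the tumor contribution is scaled by
    ``(1 - hyper_attenuation)``, emulating the empirical loss of
    hypermethylated tissue signal in plasma.  Counts are redrawn
    beta-binomially.  Both tracks must share the same CpG grid.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    if not 0.0 <= hyper_attenuation <= 1.0:
        raise ValueError("hyper_attenuation must lie in [0, 1]")
    if tumor.chroms != background.chroms:
        raise ValueError("tumor and background tracks have different chromosomes")
    cfg = SimulationConfig(mean_coverage=mean_coverage,
                           coverage_dispersion=coverage_dispersion,
                           beta_precision=beta_precision)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    frames = []
    for chrom in tumor.chroms:
        pos_t = tumor.positions(chrom)
        pos_b = background.positions(chrom)
        if len(pos_t) != len(pos_b) or not np.array_equal(pos_t, pos_b):
            raise ValueError(f"CpG grids differ on {chrom}")
        bt = tumor.betas(chrom)
        bb = background.betas(chrom)
        bt = np.where(np.isnan(bt), np.where(np.isnan(bb), 0.5, bb), bt)
        bb = np.where(np.isnan(bb), bt, bb)
        f = np.full(len(pos_t), float(tumor_fraction))
        for reg in hyper_regions:
            if reg.chrom != chrom:
                continue
            lo, hi = np.searchsorted(pos_t, [reg.start, reg.end])
            f[lo:hi] = tumor_fraction * (1.0 - hyper_attenuation)
        mix = f * bt + (1.0 - f) * bb
        n_meth, n_unmeth = _draw_counts(mix, cfg, rng)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos_t, "n_meth": n_meth, "n_unmeth": n_unmeth,
        }))
    sid = sample_id or f"{tumor.sample_id}-cf"
    return MethylomeTrack(sid, pd.concat(frames, ignore_index=True), validate=False)


def simulate_plasma_cohort(
    tracks: list[MethylomeTrack],
    truth: SimTruth,
    config: SimulationConfig,
    n_healthy: int = 3,
) -> tuple[list[MethylomeTrack], list[MethylomeTrack]]:
    """Patient plasma (tumor/leukocyte mixtures) plus healthy plasma samples.

    Each tumor with a matched normal contributes one plasma sample mixed at
    ``config.cfdna_tumor_fraction``; healthy plasma samples are independent
    redraws of the background methylome.  Mixing fractions are recorded in
    ``truth.cfdna_fractions``.
    """
    by_id = {t.sample_id: t for t in tracks}
    hyper = [r for r in truth.shared_regions if r.direction == "hyper"]
    sheet = truth.sample_sheet
    paired = sheet[sheet["role"] == "tumor"].merge(
        sheet[sheet["role"] == "normal"][["patient_id"]], on="patient_id")
    plasma = []
    for k, row in enumerate(paired.itertuples(index=False)):
        bg = simulate_background_track(config, f"BG-{row.sample_id}",
                                       seed=config.seed * 1000 + k)
        cf = simulate_cfdna(
            by_id[row.sample_id], bg, config.cfdna_tumor_fraction,
            config.cfdna_hyper_attenuation, seed=config.seed * 1000 + 500 + k,
            hyper_regions=hyper, mean_coverage=config.mean_coverage,
            coverage_dispersion=config.coverage_dispersion,
            beta_precision=config.beta_precision,
            sample_id=f"{row.sample_id}-cf",
        )
        truth.cfdna_fractions[cf.sample_id] = config.cfdna_tumor_fraction
        plasma.append(cf)
    healthy = [
        simulate_background_track(config, f"HP{j:02d}",
                                  seed=config.seed * 1000 + 900 + j)
        for j in range(n_healthy)
    ]
    for h in healthy:
        truth.cfdna_fractions[h.sample_id] = 0.0
    return plasma, healthy
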