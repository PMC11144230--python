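"""End-to-end orchestration: simulate -> DMRs -> mDMRs -> matrix -> CV.

Stages run in dependency order, each writing its outputs under the run
directory; a stage whose outputs already exist is skipped (resumable runs),
and a JSON manifest records parameters, input hashes and outputs per stage.
All randomness flows from one global seed through per-stage derived seeds,
so partial re-runs reproduce identical bytes for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, dmrcall, mdmr, methio, simcohort

log = logging.getLogger("mdmrkit")

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "outdir": "mdmrkit_run",
    "cohort": {
        "n_chromosomes": 4,
        "chrom_length_bp": 3_000_000,
        "n_cpgs_per_chrom": 6_000,
        "n_tumor_samples": 12,
        "n_normal_samples": 6,
        "mean_coverage": 30.0,
        "n_hypo_regions": 20,
        "n_hyper_regions": 20,
        "carrier_fraction": 1.0,
        "private_region_rate": 2.0,
    },
    "dmr": {"max_cpg_gap": 300, "min_cpgs": 3, "min_coverage": 5,
            "p_threshold": 0.05, "delta_threshold": 0.15},
    "mdmr": {"fraction": 0.70, "merge_gap_bp": 500},
    "classify": {"n_repeats": 10, "n_folds": 3, "min_coverage": 5},
    "concord": {"enabled": False, "min_shared_cpgs": 3, "tumor_fraction": 0.2},
    "pmd": {"enabled": False, "bin_bp": 10_000, "min_width": 1_000_000},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage derived seed: stable hash of (global seed, stage name)."""
    return (int(global_seed) * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful runner; see :func:`run_pipeline` for the one-call form."""

    def __init__(self, config: dict, force: bool = False):
        self.cfg = config
        self.outdir = Path(config["outdir"])
        self.force = force
        self.manifest: dict = {"seed": config["seed"], "stages": {}}

    # -- helpers ----------------------------------------------------------
    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def _done(self, outputs: list[Path]) -> bool:
        return (not self.force) and all(p.exists() for p in outputs)

    # -- stages -----------------------------------------------------------
    def simulate(self) -> None:
        c = self.cfg["cohort"]
        tracks_dir = self.outdir / "tracks"
        sheet_path = self.outdir / "sample_sheet.tsv"
        truth_path = self.outdir / "truth_regions.bed"
        tracks_dir.mkdir(parents=True, exist_ok=True)
        seed = stage_seed(self.cfg["seed"], "simulate")
        base = simcohort.SimulationConfig(
            seed=seed,
            n_chromosomes=c["n_chromosomes"], chrom_length_bp=c["chrom_length_bp"],
            n_cpgs_per_chrom=c["n_cpgs_per_chrom"],
            n_tumor_samples=c["n_tumor_samples"], n_normal_samples=c["n_normal_samples"],
            mean_coverage=c["mean_coverage"],
            planted_private_region_rate=c.get("private_region_rate", 0.0),
        )
        grid = simcohort.cpg_grid(base)
        regions = simcohort.design_shared_regions(
            grid, c["n_hypo_regions"], c["n_hyper_regions"],
            carrier_fraction=c.get("carrier_fraction", 1.0), seed=seed)
        config = dataclasses.replace(base, planted_shared_regions=regions)
        outputs = [sheet_path, truth_path]
        sheet = simcohort.build_sample_sheet(config)
        outputs += [tracks_dir / f"{sid}.cov" for sid in sheet["sample_id"]]
        if self._done(outputs):
            log.info("simulate: outputs present, skipping")
            return
        tracks, truth = simcohort.simulate_cohort(config)
        for t in tracks:
            methio.write_coverage_file(t, tracks_dir / f"{t.sample_id}.cov")
        truth.sample_sheet.to_csv(sheet_path, sep="\t", index=False)
        tf = truth.regions_frame()
        tf["name"] = tf["direction"]
        tf["score"] = (100 * (tf["beta_tumor"] - tf["beta_normal"]).abs()).round().astype(int)
        methio.write_regions_bed(tf, truth_path, extra_cols=["beta_normal", "beta_tumor"])
        self._record("simulate", c, outputs)
        log.info("simulate: %d tracks, %d planted regions", len(tracks), len(regions))

    def _load_tracks(self) -> tuple[dict[str, methio.MethylomeTrack], pd.DataFrame]:
        sheet = pd.read_csv(self.outdir / "sample_sheet.tsv", sep="\t")
        tracks = {
            sid: methio.read_coverage_file(self.outdir / "tracks" / f"{sid}.cov", sid)
            for sid in sheet["sample_id"]
        }
        return tracks, sheet

    def call_dmrs(self) -> None:
        dmr_dir = self.outdir / "dmrs"
        dmr_dir.mkdir(exist_ok=True)
        tracks, sheet = self._load_tracks()
        plan = dmrcall.plan_comparators(sheet)
        outputs = [dmr_dir / f"{sid}.tsv" for sid in plan]
        if self._done(outputs):
            log.info("call-dmrs: outputs present, skipping")
            return
        params = dmrcall.DMRParams(**{k: v for k, v in self.cfg["dmr"].items()})
        for sid, controls in plan.items():
            dset = dmrcall.call_dmrs(tracks[sid], [tracks[c] for c in controls],
                                     params, sample_id=sid)
            dmrcall.write_dmr_set(dset, dmr_dir / f"{sid}.tsv")
            log.info("call-dmrs: %s vs %s -> %d DMRs", sid, controls, len(dset))
        self._record("call_dmrs", self.cfg["dmr"], outputs)

    def derive_mdmrs(self) -> None:
        out_bed = self.outdir / "mdmrs.bed"
        out_tsv = self.outdir / "mdmrs.tsv"
        curve_tsv = self.outdir / "support_curve.tsv"
        outputs = [out_bed, out_tsv, curve_tsv]
        if self._done(outputs):
            log.info("mdmr: outputs present, skipping")
            return
        tracks, sheet = self._load_tracks()
        tumor_ids = sheet.loc[sheet["role"] == "tumor", "sample_id"]
        sets = [dmrcall.read_dmr_set(self.outdir / "dmrs" / f"{sid}.tsv", sid)
                for sid in tumor_ids]
        universe = tracks[tumor_ids.iloc[0]].cpg_positions()
        profile = mdmr.build_support_profile(sets, universe)
        threshold = mdmr.compute_support_threshold(len(sets), self.cfg["mdmr"]["fraction"])
        regions = mdmr.derive_mdmrs(profile, threshold, self.cfg["mdmr"]["merge_gap_bp"])
        regions.to_csv(out_tsv, sep="\t", index=False)
        mdmr.write_mdmrs_bed(regions, out_bed)
        mdmr.support_curve(profile, self.cfg["mdmr"]["merge_gap_bp"]).to_csv(
            curve_tsv, sep="\t", index=False)
        self._record("mdmr", {**self.cfg["mdmr"], "threshold": threshold}, outputs)
        log.info("mdmr: %d consensus regions at support >= %d", len(regions), threshold)

    def build_matrix(self) -> None:
        out = self.outdir / "matrix.tsv"
        if self._done([out]):
            log.info("matrix: outputs present, skipping")
            return
        tracks, sheet = self._load_tracks()
        regions = pd.read_csv(self.outdir / "mdmrs.tsv", sep="\t")
        if regions.empty:
            raise RuntimeError("matrix: no mDMRs available")
        labels = sheet.set_index("sample_id")["role"]
        mat = classify.build_matrix(list(tracks.values()), regions, labels,
                                    min_coverage=self.cfg["classify"]["min_coverage"])
        mat.values.to_csv(out, sep="\t")
        self._record("matrix", {"n_regions": len(regions)}, [out])

    def classify_stage(self) -> None:
        report = self.outdir / "cv_report.tsv"
        roc = self.outdir / "roc_points.tsv"
        if self._done([report, roc]):
            log.info("classify: outputs present, skipping")
            return
        _, sheet = self._load_tracks()
        values = pd.read_csv(self.outdir / "matrix.tsv", sep="\t", index_col=0)
        regions = pd.read_csv(self.outdir / "mdmrs.tsv", sep="\t")
        labels = sheet.set_index("sample_id")["role"]
        mat = classify.RegionBetaMatrix(values, labels, regions)
        res = classify.cross_validate(
            mat, n_repeats=self.cfg["classify"]["n_repeats"],
            n_folds=self.cfg["classify"]["n_folds"],
            seed=stage_seed(self.cfg["seed"], "classify"))
        summary = res.per_fold_auc.copy()
        summary.attrs["auc"] = res.auc
        with open(report, "w") as fh:
            fh.write(f"# pooled_auc\t{res.auc:.4f}\tci\t{res.auc_ci[0]:.4f}\t{res.auc_ci[1]:.4f}\n")
            summary.to_csv(fh, sep="\t", index=False)
        res.roc_points.to_csv(roc, sep="\t", index=False)
        self._record("classify", self.cfg["classify"], [report, roc])
        log.info("classify: pooled AUC %.3f (CI %.3f-%.3f)", res.auc, *res.auc_ci)

    def run(self) -> dict:
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in (self.simulate, self.call_dmrs, self.derive_mdmrs,
                      self.build_matrix, self.classify_stage):
            try:
                stage()
            except Exception:
                log.error("pipeline halted at stage %r", stage.__name__)
                raise
        manifest_path = self.outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return self.manifest


def run_pipeline(config, force: bool = False) -> dict:
    """Run the full synthetic-cohort pipeline from a config dict or YAML path."""
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    tracks_parent = outdir.parent
    if not tracks_parent.exists():
        raise FileNotFoundError(f"output parent directory missing: {tracks_parent}")
    return PipelineRun(cfg, force=force).run()
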