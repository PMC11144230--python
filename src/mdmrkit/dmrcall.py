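"""Per-sample tumor-vs-control DMR calling.

A transparent sign-run segmentation with rank-based testing: candidate
regions are maximal runs of consecutive CpGs whose case-vs-control beta
difference keeps a constant sign and exceeds a per-CpG seed threshold;
each candidate is scored by a two-sided Mann-Whitney U test comparing the
pooled per-CpG betas of the case group against the control group inside
the region.  Retained DMRs satisfy p < 0.05, |delta beta| > 0.15, a minimum
CpG count, and exclude the sex chromosomes.

Control groups follow a comparator plan: matched normal where available,
otherwise a pool of same-diagnosis normals, otherwise all normals; pooled
controls are combined at the read-count level (count-summed per CpG), not
as a mean of means, which stabilizes low-coverage CpGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats

from .methio import SEX_CHROMS, MethylomeTrack

DMR_COLUMNS = ["chrom", "start", "end", "n_cpgs", "mean_beta_case",
               "mean_beta_control", "delta_beta", "p_value", "direction"]


@dataclass(frozen=True)
class DMRParams:
    """Segmentation and retention parameters.

    ``seed_delta`` is the per-CpG |beta difference| needed to extend a
    candidate run; ``max_cpg_gap`` bounds the genomic gap between
    consecutive run members.  Retention applies the p-value, effect-size,
    CpG-count and sex-chromosome filters.
    """

    max_cpg_gap: int = 300
    min_cpgs: int = 3
    min_coverage: int = 5
    p_threshold: float = 0.05
    delta_threshold: float = 0.15
    seed_delta: float = 0.10
    drop_sex_chroms: bool = True


@dataclass
class DMRSet:
    """Sorted, non-overlapping DMRs of one case sample."""

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.empty:
            self.df = pd.DataFrame(columns=DMR_COLUMNS)
        self.df = self.df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping DMRs within set on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_hypo(self) -> int:
        return int((self.df["direction"] == "hypo").sum())

    @property
    def n_hyper(self) -> int:
        return int((self.df["direction"] == "hyper").sum())


def plan_comparators(sample_sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Assign a control sample set to every tumor sample.

    Preference order: normals of the same patient; else normals with the
    same diagnosis; else all normals.  Raises when the cohort contains no
    normal samples.
    """
    normals = sample_sheet[sample_sheet["role"] == "normal"]
    if normals.empty:
        raise ValueError("cohort contains no normal samples")
    plan: dict[str, list[str]] = {}
    for row in sample_sheet[sample_sheet["role"] == "tumor"].itertuples(index=False):
        matched = normals[normals["patient_id"] == row.patient_id]
        if len(matched):
            plan[row.sample_id] = matched["sample_id"].tolist()
            continue
        same_dx = normals[normals["diagnosis"] == row.diagnosis]
        if len(same_dx):
            plan[row.sample_id] = same_dx["sample_id"].tolist()
        else:
            plan[row.sample_id] = normals["sample_id"].tolist()
    return plan


def _shared_positions(tracks: list[MethylomeTrack]) -> dict[str, np.ndarray]:
    chroms = reduce(lambda a, b: [c for c in a if c in b],
                    [t.chroms for t in tracks])
    out = {}
    for chrom in chroms:
        pos = reduce(np.intersect1d, [t.positions(chrom) for t in tracks])
        if len(pos):
            out[chrom] = pos
    return out


def _aligned_counts(track: MethylomeTrack, chrom: str, universe: np.ndarray):
    pos = track.positions(chrom)
    idx = np.searchsorted(pos, universe)
    m, u = track.counts(chrom)
    return m[idx].astype(float), u[idx].astype(float)


def _pooled_beta(tracks, chrom, universe, min_coverage):
    """Count-summed beta across tracks; NaN below the coverage floor."""
    M = np.zeros(len(universe))
    U = np.zeros(len(universe))
    for t in tracks:
        m, u = _aligned_counts(t, chrom, universe)
        M += m
        U += u
    cov = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(cov >= min_coverage, M / np.where(cov > 0, cov, 1), np.nan)
    return b


def _per_track_betas(tracks, chrom, universe, min_coverage):
    """(n_tracks, n_cpgs) matrix of per-track betas, NaN below coverage."""
    out = np.empty((len(tracks), len(universe)))
    for i, t in enumerate(tracks):
        m, u = _aligned_counts(t, chrom, universe)
        cov = m + u
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(cov >= min_coverage, m / np.where(cov > 0, cov, 1), np.nan)
    return out


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small groups, normal
    approximation with tie correction otherwise."""
    if len(x) == 0 or len(y) == 0:
        return math.nan
    method = "exact" if min(len(x), len(y)) < 8 and len(x) * len(y) <= 2000 else "asymptotic"
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    except ValueError:
        return math.nan


def score_window(
    case_tracks: list[MethylomeTrack],
    control_tracks: list[MethylomeTrack],
    chrom: str,
    start: int,
    end: int,
    params: DMRParams = DMRParams(),
) -> dict:
    """Score one fixed window with the DMR retention statistics.

    Returns the Mann-Whitney p-value on pooled per-CpG betas, the region
    delta beta (case minus control, on count-pooled per-CpG betas), the CpG
    count and the retention verdict.  Used by the caller internally and as
    a public hook for scoring externally supplied windows.
    """
    universe = _shared_positions(case_tracks + control_tracks)
    pos = universe.get(chrom, np.array([], dtype=np.int64))
    lo, hi = np.searchsorted(pos, [start, end])
    window = pos[lo:hi]
    if len(window) == 0:
        return {"p_value": math.nan, "delta_beta": math.nan, "n_cpgs": 0,
                "retained": False, "mean_beta_case": math.nan,
                "mean_beta_control": math.nan}
    case_b = _per_track_betas(case_tracks, chrom, window, params.min_coverage)
    ctrl_b = _per_track_betas(control_tracks, chrom, window, params.min_coverage)
    case_pool = _pooled_beta(case_tracks, chrom, window, params.min_coverage)
    ctrl_pool = _pooled_beta(control_tracks, chrom, window, params.min_coverage)
    x = case_b[~np.isnan(case_b)]
    y = ctrl_b[~np.isnan(ctrl_b)]
    p = mann_whitney_p(x, y)
    mb_case = float(np.nanmean(case_pool)) if np.isfinite(case_pool).any() else math.nan
    mb_ctrl = float(np.nanmean(ctrl_pool)) if np.isfinite(ctrl_pool).any() else math.nan
    delta = mb_case - mb_ctrl
    retained = (
        np.isfinite(p) and p < params.p_threshold
        and np.isfinite(delta) and abs(delta) > params.delta_threshold
        and len(window) >= params.min_cpgs
        and not (params.drop_sex_chroms and chrom in SEX_CHROMS)
    )
    return {"p_value": p, "delta_beta": delta, "n_cpgs": int(len(window)),
            "retained": bool(retained), "mean_beta_case": mb_case,
            "mean_beta_control": mb_ctrl}


def _candidate_runs(diff: np.ndarray, pos: np.ndarray, params: DMRParams):
    """Maximal same-sign seed runs: consecutive CpGs, each with
    |diff| >= seed_delta, constant sign, genomic step <= max_cpg_gap."""
    sign = np.zeros(len(diff), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        sign[diff >= params.seed_delta] = 1
        sign[diff <= -params.seed_delta] = -1
    idx = np.flatnonzero(sign != 0)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(idx) != 1)
        | (sign[idx[1:]] != sign[idx[:-1]])
        | ((pos[idx[1:]] - pos[idx[:-1]]) > params.max_cpg_gap)
    )
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(idx) - 1]
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def call_dmrs(
    case_tracks: list[MethylomeTrack] | MethylomeTrack,
    control_tracks: list[MethylomeTrack] | MethylomeTrack,
    params: DMRParams = DMRParams(),
    sample_id: str | None = None,
) -> DMRSet:
    """Call DMRs for a case sample (or pooled case group) against controls.

    The CpG universe is the intersection of all tracks' positions.  Every
    retained DMR satisfies all filters; output is independent of the order
    of the input tracks.
    """
    if isinstance(case_tracks, MethylomeTrack):
        case_tracks = [case_tracks]
    if isinstance(control_tracks, MethylomeTrack):
        control_tracks = [control_tracks]
    if not case_tracks or not control_tracks:
        raise ValueError("need at least one case and one control track")
    if sample_id is None:
        sample_id = case_tracks[0].sample_id
    universe = _shared_positions(case_tracks + control_tracks)
    if not universe:
        raise ValueError("empty shared CpG universe between case and control tracks")

    rows = []
    for chrom, pos in universe.items():
        if params.drop_sex_chroms and chrom in SEX_CHROMS:
            continue
        case_pool = _pooled_beta(case_tracks, chrom, pos, params.min_coverage)
        ctrl_pool = _pooled_beta(control_tracks, chrom, pos, params.min_coverage)
        diff = case_pool - ctrl_pool
        case_b = _per_track_betas(case_tracks, chrom, pos, params.min_coverage)
        ctrl_b = _per_track_betas(control_tracks, chrom, pos, params.min_coverage)
        for i0, i1 in _candidate_runs(diff, pos, params):
            n_cpgs = i1 - i0 + 1
            if n_cpgs < params.min_cpgs:
                continue
            x = case_b[:, i0:i1 + 1].ravel()
            y = ctrl_b[:, i0:i1 + 1].ravel()
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            p = mann_whitney_p(x, y)
            if not np.isfinite(p) or p >= params.p_threshold:
                continue
            mb_case = float(np.nanmean(case_pool[i0:i1 + 1]))
            mb_ctrl = float(np.nanmean(ctrl_pool[i0:i1 + 1]))
            delta = mb_case - mb_ctrl
            if not abs(delta) > params.delta_threshold:
                continue
            rows.append({
                "chrom": chrom, "start": int(pos[i0]), "end": int(pos[i1]) + 1,
                "n_cpgs": n_cpgs, "mean_beta_case": mb_case,
                "mean_beta_control": mb_ctrl, "delta_beta": delta,
                "p_value": p, "direction": "hyper" if delta > 0 else "hypo",
            })
    df = pd.DataFrame(rows, columns=DMR_COLUMNS)
    _assert_retention(df, params)
    return DMRSet(sample_id, df)


def _assert_retention(df: pd.DataFrame, params: DMRParams) -> None:
    if df.empty:
        return
    assert (df["p_value"] < params.p_threshold).all()
    assert (df["delta_beta"].abs() > params.delta_threshold).all()
    assert (df["n_cpgs"] >= params.min_cpgs).all()
    if params.drop_sex_chroms:
        assert not df["chrom"].isin(SEX_CHROMS).any()
    assert ((df["delta_beta"] > 0) == (df["direction"] == "hyper")).all()


def summarize_directionality(dmrset: DMRSet) -> tuple[float, float]:
    """(hypo_fraction, hyper_fraction) by DMR count; NaN for an empty set."""
    n = len(dmrset)
    if n == 0:
        return (math.nan, math.nan)
    return (dmrset.n_hypo / n, dmrset.n_hyper / n)


def write_dmr_set(dmrset: DMRSet, path) -> None:
    """Write a DMR set as a headered TSV."""
    out = dmrset.df.copy()
    out.insert(0, "sample_id", dmrset.sample_id)
    out.to_csv(str(path), sep="\t", index=False)


def read_dmr_set(path, sample_id: str | None = None) -> DMRSet:
    df = pd.read_csv(str(path), sep="\t")
    sid = sample_id or (str(df["sample_id"].iloc[0]) if len(df) else "unknown")
    return DMRSet(sid, df[DMR_COLUMNS] if len(df) else df)
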