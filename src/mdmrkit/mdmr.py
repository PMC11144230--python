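"""Consensus "minimally differentially methylated regions" (mDMRs).

Given many per-sample DMR sets on a shared CpG universe, each CpG locus is
scored by the number of samples with a same-direction DMR overlapping it
(a sample contributes at most one support unit per locus and direction).
Loci reaching a support threshold — by default the ceiling of 70% of the
cohort — are chain-merged while consecutive kept loci are within 500 bp,
yielding one consensus region per chain, anchored at its first and last
member CpG.

Also provides the across-sample variance ranking used to pick highly
variable regions for clustering-style analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmrcall import DMRSet

MDMR_COLUMNS = ["chrom", "start", "end", "direction", "n_cpgs",
                "min_support", "max_support", "width_bp"]


@dataclass
class SupportProfile:
    """Per-CpG cross-sample DMR support counts, by direction.

    ``df`` has one row per universe CpG: ``chrom, pos, hypo_support,
    hyper_support``; ``n_samples`` is the number of contributing DMR sets.
    """

    df: pd.DataFrame
    n_samples: int

    def chrom_arrays(self, chrom: str):
        sub = self.df[self.df["chrom"] == chrom]
        return (sub["pos"].to_numpy(), sub["hypo_support"].to_numpy(),
                sub["hyper_support"].to_numpy())


def build_support_profile(
    dmr_sets: list[DMRSet],
    universe: dict[str, np.ndarray],
) -> SupportProfile:
    """Count, per universe locus and direction, how many samples have an
    overlapping DMR there.

    A sample with several DMRs over the same locus still contributes one
    unit (support counts samples, not DMR calls).  Duplicate sample ids
    across sets are rejected.
    """
    ids = [s.sample_id for s in dmr_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id across DMR sets")
    frames = []
    for chrom in sorted(universe):
        pos = np.asarray(universe[chrom])
        hypo = np.zeros(len(pos), dtype=np.int32)
        hyper = np.zeros(len(pos), dtype=np.int32)
        for dset in dmr_sets:
            sub = dset.df[dset.df["chrom"] == chrom]
            if sub.empty:
                continue
            cover_h = np.zeros(len(pos), bool)
            cover_H = np.zeros(len(pos), bool)
            for row in sub.itertuples(index=False):
                lo, hi = np.searchsorted(pos, [row.start, row.end])
                (cover_h if row.direction == "hypo" else cover_H)[lo:hi] = True
            hypo += cover_h
            hyper += cover_H
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "hypo_support": hypo, "hyper_support": hyper}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["chrom", "pos", "hypo_support", "hyper_support"]))
    return SupportProfile(df, len(dmr_sets))


def compute_support_threshold(n_samples: int, fraction: float) -> int:
    """Smallest integer >= fraction * n_samples (e.g. 70% of 31 -> 22)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    # tolerance keeps exact products (0.70 * 10 = 7) from ceiling up
    return int(math.ceil(fraction * n_samples - 1e-9))


def _chain_merge(pos: np.ndarray, support: np.ndarray, threshold: int,
                 merge_gap_bp: int) -> list[tuple[int, int, int, int, int]]:
    """Chain kept loci transitively while steps are <= merge_gap_bp.

    Yields (start, end, n_cpgs, min_support, max_support) per chain, with
    end = last member CpG + 1.
    """
    keep = support >= threshold
    kp = pos[keep]
    ks = support[keep]
    if len(kp) == 0:
        return []
    breaks = np.flatnonzero(np.diff(kp) > merge_gap_bp)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(kp) - 1]
    return [
        (int(kp[s]), int(kp[e]) + 1, int(e - s + 1),
         int(ks[s:e + 1].min()), int(ks[s:e + 1].max()))
        for s, e in zip(starts, ends)
    ]


def derive_mdmrs(
    profile: SupportProfile,
    threshold: int,
    merge_gap_bp: int = 500,
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Consensus regions from a support profile, per direction independently.

    Keeps loci with support >= threshold, merges kept loci while
    consecutive ones are within ``merge_gap_bp`` (transitive chaining, so a
    region may span far more than the gap), and emits one region per chain
    with CpG-anchored boundaries.  Single-CpG regions are kept by default.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rows = []
    for chrom in profile.df["chrom"].unique():
        pos, hypo, hyper = profile.chrom_arrays(chrom)
        for direction, support in (("hypo", hypo), ("hyper", hyper)):
            for start, end, n, smin, smax in _chain_merge(pos, support, threshold, merge_gap_bp):
                if n < min_cpgs:
                    continue
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "direction": direction, "n_cpgs": n,
                             "min_support": smin, "max_support": smax,
                             "width_bp": end - start})
    df = pd.DataFrame(rows, columns=MDMR_COLUMNS)
    return df.sort_values(["chrom", "start", "direction"], kind="mergesort").reset_index(drop=True)


def support_curve(profile: SupportProfile, merge_gap_bp: int = 500) -> pd.DataFrame:
    """mDMR and kept-CpG counts at every threshold 1..n_samples.

    Columns: ``threshold, n_hypo_mdmrs, n_hyper_mdmrs, n_hypo_cpgs,
    n_hyper_cpgs``.  Kept-CpG counts are non-increasing in the threshold;
    region counts usually are too but may transiently rise when a region
    splits.
    """
    rows = []
    hypo = profile.df["hypo_support"].to_numpy()
    hyper = profile.df["hyper_support"].to_numpy()
    for n in range(1, profile.n_samples + 1):
        m = derive_mdmrs(profile, n, merge_gap_bp)
        rows.append({
            "threshold": n,
            "n_hypo_mdmrs": int((m["direction"] == "hypo").sum()),
            "n_hyper_mdmrs": int((m["direction"] == "hyper").sum()),
            "n_hypo_cpgs": int((hypo >= n).sum()),
            "n_hyper_cpgs": int((hyper >= n).sum()),
        })
    return pd.DataFrame(rows)


def select_variable_regions(values: pd.DataFrame, top_fraction: float = 0.025) -> pd.Index:
    """Indices of the most variable regions of a regions x samples matrix.

    Regions are ranked by across-sample variance of mean beta (NaN-aware,
    ddof=1; regions with fewer than two observed samples rank last) and the
    top ``ceil(top_fraction * n_regions)`` are returned.  An all-constant
    matrix yields an empty selection with a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    arr = values.to_numpy(float)
    n_obs = np.sum(~np.isnan(arr), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(arr, axis=1, ddof=1)
    var = np.where(n_obs >= 2, var, -np.inf)
    if np.nanmax(np.where(np.isfinite(var), var, 0)) <= 0:
        warnings.warn("all regions constant across samples; empty selection", stacklevel=2)
        return values.index[:0]
    k = math.ceil(top_fraction * len(values))
    order = np.argsort(-var, kind="stable")[:k]
    return values.index[np.sort(order)]


def write_mdmrs_bed(mdmrs: pd.DataFrame, path) -> None:
    """BED6+ export: name=direction, score=max_support, extra n_cpgs/min_support."""
    bed = pd.DataFrame({
        "chrom": mdmrs["chrom"], "start": mdmrs["start"], "end": mdmrs["end"],
        "name": mdmrs["direction"], "score": mdmrs["max_support"], "strand": ".",
        "n_cpgs": mdmrs["n_cpgs"], "min_support": mdmrs["min_support"],
    })
    bed.to_csv(str(path), sep="\t", header=False, index=False)
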