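"""Megabase-scale hypomethylated domain detection and classification.

A binned run-segmentation scanner: the genome is tiled into fixed bins
(default 10 kb), a bin is "low" when its mean CpG beta falls below a cutoff
(default 0.7), and maximal runs of low bins — tolerating short interruptions
— that exceed a minimum width (default 1 Mb) become domains.  Each domain
is classified by its mean CpG beta: below 0.2 it is a methylation desert,
between 0.2 and 0.7 a partially methylated domain (PMD); deserts are carved
out of the PMD universe, never double-reported.  Consensus regions are the
maximal intervals covered by domain calls in more than a fraction (default
50%) of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methio import MethylomeTrack

DOMAIN_COLUMNS = ["chrom", "start", "end", "mean_beta", "sd_beta",
                  "n_cpgs", "width_bp", "klass"]

DESERT_BETA = 0.2
PMD_BETA = 0.7


@dataclass(frozen=True)
class DomainParams:
    bin_bp: int = 10_000
    min_cpgs_per_bin: int = 5
    low_beta_cutoff: float = 0.7
    max_high_bin_run: int = 2
    min_anchor_bins: int = 3
    min_width: int = 1_000_000


def classify_domain(mean_beta: float) -> str | None:
    """desert below 0.2; pmd in [0.2, 0.7); None (excluded) at or above 0.7."""
    if not np.isfinite(mean_beta):
        return None
    if mean_beta < DESERT_BETA:
        return "desert"
    if mean_beta < PMD_BETA:
        return "pmd"
    return None


def _bin_means(pos: np.ndarray, betas: np.ndarray, bin_bp: int,
               min_cpgs: int) -> tuple[np.ndarray, np.ndarray]:
    """(bin index array, bin mean beta) over bins with enough covered CpGs;
    under-populated bins get NaN means."""
    ok = ~np.isnan(betas)
    if not ok.any():
        return np.array([], dtype=np.int64), np.array([])
    bins = pos[ok] // bin_bp
    b = betas[ok]
    n_bins = int(bins.max()) + 1
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=b, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts >= min_cpgs, sums / np.maximum(counts, 1), np.nan)
    return np.arange(n_bins), means


def _low_runs(low: np.ndarray, max_interrupt: int, min_anchor: int = 3):
    """Maximal runs of True bins tolerating interior runs of <= max_interrupt
    False bins.

    Each run boundary must be anchored on >= ``min_anchor`` consecutive low
    bins: short low blips at a run edge — typically lone unmethylated
    CpG-island bins, which are low-beta everywhere and carry no domain
    evidence — are trimmed rather than allowed to extend the domain by up
    to the interruption tolerance.
    """
    idx = np.flatnonzero(low)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > max_interrupt + 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(idx) - 1]
    for s, e in zip(starts, ends):
        run = idx[s:e + 1]
        # consecutive-bin groups within the run
        grp_breaks = np.flatnonzero(np.diff(run) > 1)
        g_starts = np.r_[0, grp_breaks + 1]
        g_ends = np.r_[grp_breaks, len(run) - 1]
        sizes = g_ends - g_starts + 1
        anchored = np.flatnonzero(sizes >= min_anchor)
        if len(anchored) == 0:
            continue
        lo = int(run[g_starts[anchored[0]]])
        hi = int(run[g_ends[anchored[-1]]])
        if hi > lo:
            yield lo, hi


def scan_domains(track: MethylomeTrack, params: DomainParams = DomainParams()) -> pd.DataFrame:
    """Detect hypomethylated domains in one sample's methylome.

    Returns a domain table (``DOMAIN_COLUMNS``); domains at or above the
    PMD beta ceiling (0.7) after averaging member CpGs are dropped.  Mean
    and sd are computed over the member CpG betas, not over bin means.
    """
    rows = []
    for chrom in track.chroms:
        pos = track.positions(chrom)
        betas = track.betas(chrom)
        _, means = _bin_means(pos, betas, params.bin_bp, params.min_cpgs_per_bin)
        if len(means) == 0:
            continue
        low = np.zeros(len(means), bool)
        with np.errstate(invalid="ignore"):
            low[np.nan_to_num(means, nan=np.inf) < params.low_beta_cutoff] = True
        for b0, b1 in _low_runs(low, params.max_high_bin_run, params.min_anchor_bins):
            start = b0 * params.bin_bp
            end = (b1 + 1) * params.bin_bp
            if end - start < params.min_width:
                continue
            lo, hi = np.searchsorted(pos, [start, end])
            member = betas[lo:hi]
            member = member[~np.isnan(member)]
            if len(member) == 0:
                continue
            mean_beta = float(member.mean())
            klass = classify_domain(mean_beta)
            if klass is None:
                continue
            rows.append({
                "chrom": chrom, "start": int(start), "end": int(end),
                "mean_beta": mean_beta,
                "sd_beta": float(member.std(ddof=1)) if len(member) > 1 else 0.0,
                "n_cpgs": int(len(member)), "width_bp": int(end - start),
                "klass": klass,
            })
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def consensus_domains(
    domain_sets: dict[str, pd.DataFrame],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Regions supported by domain calls in more than ``min_fraction`` of samples.

    Base-resolution sweep over all samples' domains; maximal intervals with
    supporting fraction strictly greater than the threshold are emitted,
    with contiguous qualifying intervals merged.  ``n_supporting_samples``
    and ``supporting_fraction`` report the peak support inside each region.
    """
    if len(domain_sets) < 2:
        raise ValueError("consensus requires at least two samples")
    n = len(domain_sets)
    need = min_fraction * n
    rows = []
    chroms = sorted({c for df in domain_sets.values() for c in df["chrom"].unique()})
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for df in domain_sets.values():
            sub = df[df["chrom"] == chrom]
            for row in sub.itertuples(index=False):
                events.append((int(row.start), 1))
                events.append((int(row.end), -1))
        if not events:
            continue
        events.sort()
        bps = np.unique([e[0] for e in events])
        depth = 0
        cur_start = None
        cur_peak = 0
        i = 0
        for bp in bps:
            while i < len(events) and events[i][0] == bp:
                depth += events[i][1]
                i += 1
            qualifying = depth > need
            if qualifying and cur_start is None:
                cur_start = int(bp)
                cur_peak = depth
            elif qualifying:
                cur_peak = max(cur_peak, depth)
            elif cur_start is not None:
                rows.append({"chrom": chrom, "start": cur_start, "end": int(bp),
                             "n_supporting_samples": cur_peak,
                             "supporting_fraction": cur_peak / n})
                cur_start = None
                cur_peak = 0
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_supporting_samples", "supporting_fraction"])


def write_domains_bed(domains: pd.DataFrame, path) -> None:
    """BED6+ export with score = round(100 * mean beta)."""
    bed = pd.DataFrame({
        "chrom": domains["chrom"], "start": domains["start"], "end": domains["end"],
        "name": domains["klass"],
        "score": (100 * domains["mean_beta"]).round().astype(int),
        "strand": ".",
        "sd_beta": domains["sd_beta"].round(4), "n_cpgs": domains["n_cpgs"],
    })
    bed.to_csv(str(path), sep="\t", header=False, index=False)
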