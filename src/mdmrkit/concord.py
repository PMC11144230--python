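"""Tissue <-> cell-free DNA DMR concordance.

Two DMRs from different samples are called overlapping when they share at
least three CpG loci (present with coverage in both samples) inside their
positional intersection and have the same direction.  The per-patient
report gives the percent of cfDNA DMRs with at least one qualifying tissue
overlap (cfDNA count is the denominator), plus R^2 and Spearman correlation
of the paired delta betas over intersecting regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmrcall import DMRSet


@dataclass(frozen=True)
class OverlapCall:
    """One qualifying pair: row indices into the two DMR sets."""

    idx_a: int
    idx_b: int
    n_shared_cpgs: int
    same_direction: bool = True


@dataclass
class ConcordanceReport:
    n_dmrs_a: int
    n_dmrs_b: int
    n_overlapping: int
    pct_overlap: float
    delta_pairs: pd.DataFrame  # delta_a, delta_b per overlap call
    r_squared: float
    spearman_rho: float


def overlapping_dmrs(
    set_a: DMRSet,
    set_b: DMRSet,
    min_shared_cpgs: int = 3,
    cpgs_a: dict[str, np.ndarray] | None = None,
    cpgs_b: dict[str, np.ndarray] | None = None,
) -> list[OverlapCall]:
    """All same-direction DMR pairs sharing >= min_shared_cpgs CpG loci.

    ``cpgs_a``/``cpgs_b`` are each sample's covered CpG positions per
    chromosome (see :meth:`MethylomeTrack.cpg_positions`); shared CpGs are
    loci present in both universes inside the positional intersection.
    An A-region may match multiple B-regions; membership is symmetric.
    """
    if cpgs_a is None or cpgs_b is None:
        raise ValueError("both samples' CpG universes are required to count shared CpGs")
    calls: list[OverlapCall] = []
    dfa, dfb = set_a.df, set_b.df
    empty = np.array([], dtype=np.int64)
    for chrom in np.intersect1d(dfa["chrom"].unique(), dfb["chrom"].unique()):
        shared = np.intersect1d(cpgs_a.get(chrom, empty), cpgs_b.get(chrom, empty))
        sub_a = dfa[dfa["chrom"] == chrom]
        sub_b = dfb[dfb["chrom"] == chrom]
        for ia, ra in sub_a.iterrows():
            for ib, rb in sub_b.iterrows():
                if ra["direction"] != rb["direction"]:
                    continue
                lo = max(ra["start"], rb["start"])
                hi = min(ra["end"], rb["end"])
                if hi <= lo:
                    continue
                n = int(np.searchsorted(shared, hi) - np.searchsorted(shared, lo))
                if n >= min_shared_cpgs:
                    calls.append(OverlapCall(int(ia), int(ib), n))
    return calls


def concordance_report(
    set_cf: DMRSet,
    set_tissue: DMRSet,
    min_shared_cpgs: int = 3,
    cpgs_cf: dict[str, np.ndarray] | None = None,
    cpgs_tissue: dict[str, np.ndarray] | None = None,
    denominator: str = "cf",
) -> ConcordanceReport:
    """Patient-level concordance between cfDNA and tissue DMR sets.

    ``pct_overlap`` is the fraction (x100) of the numerator set's DMRs with
    at least one qualifying overlap in the other set; cfDNA is the
    numerator by default (``denominator='tissue'`` switches it).  Delta-beta
    pairs contribute one point per overlap call; R^2 comes from an ordinary
    least-squares fit (with intercept) of the tissue delta on the cfDNA
    delta.  With fewer than three pairs the correlations are NaN but the
    counts are still reported.  ``pct_overlap`` is 0 when the numerator set
    is empty.
    """
    calls = overlapping_dmrs(set_cf, set_tissue, min_shared_cpgs, cpgs_cf, cpgs_tissue)
    if denominator == "cf":
        n_num = len(set_cf)
        hit = {c.idx_a for c in calls}
    elif denominator == "tissue":
        n_num = len(set_tissue)
        hit = {c.idx_b for c in calls}
    else:
        raise ValueError("denominator must be 'cf' or 'tissue'")
    pct = 100.0 * len(hit) / n_num if n_num else 0.0
    pairs = pd.DataFrame({
        "delta_cf": [set_cf.df.loc[c.idx_a, "delta_beta"] for c in calls],
        "delta_tissue": [set_tissue.df.loc[c.idx_b, "delta_beta"] for c in calls],
    })
    if len(pairs) >= 3 and pairs["delta_cf"].nunique() > 1:
        fit = stats.linregress(pairs["delta_cf"], pairs["delta_tissue"])
        r2 = float(fit.rvalue ** 2)
        rho = float(stats.spearmanr(pairs["delta_cf"], pairs["delta_tissue"]).statistic)
    else:
        r2 = math.nan
        rho = math.nan
    return ConcordanceReport(
        n_dmrs_a=len(set_cf), n_dmrs_b=len(set_tissue),
        n_overlapping=len(hit), pct_overlap=pct,
        delta_pairs=pairs, r_squared=r2, spearman_rho=rho,
    )


def cohort_summary(reports: dict[str, ConcordanceReport]) -> pd.DataFrame:
    """Per-patient rows plus a mean/median summary of overlap and R^2."""
    rows = [
        {"patient": pid, "n_dmrs_cf": r.n_dmrs_a, "n_dmrs_tissue": r.n_dmrs_b,
         "n_overlapping": r.n_overlapping, "pct_overlap": r.pct_overlap,
         "r_squared": r.r_squared, "spearman_rho": r.spearman_rho}
        for pid, r in reports.items()
    ]
    return pd.DataFrame(rows)
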