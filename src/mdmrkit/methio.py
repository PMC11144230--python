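"""Methylome track I/O, beta values, region summaries and annotation.

The central container is :class:`MethylomeTrack`: one sample's per-CpG
methylated/unmethylated read counts, sorted by (chromosome, position) with
0-based internal coordinates.  Bismark-style coverage files (1-based,
inclusive) are the on-disk interchange format; BED output is 0-based
half-open.

The beta value of a CpG is ``n_meth / (n_meth + n_unmeth)`` and is undefined
(NaN) at zero coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("chrom", "pos", "n_meth", "n_unmeth")

#: chromosome names treated as sex chromosomes throughout the package
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start must be < end: {self}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class MethylomeTrack:
    """Per-sample ordered per-CpG counts.

    Parameters
    ----------
    sample_id :
        Identifier of the sample the track belongs to.
    df :
        DataFrame with columns ``chrom, pos, n_meth, n_unmeth``.  Rows are
        sorted and de-duplicated on (chrom, pos); counts must be
        non-negative.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame, *, validate: bool = True):
        df = df.loc[:, list(TRACK_COLUMNS)].reset_index(drop=True)
        if validate:
            if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
                raise ValueError("negative read counts in methylome track")
            if not df[["chrom", "pos"]].apply(tuple, axis=1).is_monotonic_increasing:
                df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            if df.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate (chrom, pos) records in methylome track")
        self.sample_id = sample_id
        self.df = df
        # per-chromosome row slices, in sorted order
        self._slices: dict[str, slice] = {}
        chroms = df["chrom"].to_numpy()
        if len(chroms):
            starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
            bounds = np.r_[starts, len(chroms)]
            for i, s in enumerate(starts):
                self._slices[chroms[s]] = slice(int(bounds[i]), int(bounds[i + 1]))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"MethylomeTrack({self.sample_id!r}, {len(self)} CpGs, {len(self._slices)} chroms)"

    @property
    def chroms(self) -> list[str]:
        return list(self._slices)

    def chrom_data(self, chrom: str) -> pd.DataFrame:
        sl = self._slices.get(chrom)
        if sl is None:
            return self.df.iloc[0:0]
        return self.df.iloc[sl]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chrom_data(chrom)["pos"].to_numpy()

    def counts(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.chrom_data(chrom)
        return sub["n_meth"].to_numpy(), sub["n_unmeth"].to_numpy()

    def coverage(self, chrom: str | None = None) -> np.ndarray:
        sub = self.df if chrom is None else self.chrom_data(chrom)
        return (sub["n_meth"] + sub["n_unmeth"]).to_numpy()

    def betas(self, chrom: str | None = None) -> np.ndarray:
        """Per-CpG beta values; NaN where coverage is zero."""
        sub = self.df if chrom is None else self.chrom_data(chrom)
        m = sub["n_meth"].to_numpy(float)
        cov = m + sub["n_unmeth"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(cov > 0, m / np.where(cov > 0, cov, 1), np.nan)
        return b

    def cpg_positions(self, min_coverage: int = 1) -> dict[str, np.ndarray]:
        """Covered CpG positions per chromosome (the sample's CpG universe)."""
        out = {}
        for chrom in self.chroms:
            sub = self.chrom_data(chrom)
            cov = (sub["n_meth"] + sub["n_unmeth"]).to_numpy()
            out[chrom] = sub["pos"].to_numpy()[cov >= min_coverage]
        return out


def beta(n_meth: int, n_unmeth: int) -> float:
    """Beta value of a single CpG; NaN when coverage is zero."""
    cov = n_meth + n_unmeth
    if cov <= 0:
        return math.nan
    return n_meth / cov


def read_coverage_file(path, sample_id: str | None = None) -> MethylomeTrack:
    """Read a Bismark-style coverage file into a track.

    Expected dialect: tab-separated ``chrom start end pct n_meth n_unmeth``
    with 1-based inclusive positions and ``start == end`` per CpG; ``.gz``
    transparently decompressed.  The percentage column is ignored in favor
    of the counts.  Positions are shifted to internal 0-based coordinates.
    Unsorted input is sorted with a warning; malformed or negative-count
    lines raise with the offending line number.
    """
    path = str(path)
    if sample_id is None:
        name = path.rsplit("/", 1)[-1]
        for suf in (".gz", ".cov", ".bedGraph", ".txt", ".tsv"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        sample_id = name
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
            dtype={"chrom": str}, compression="infer",
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"])
    for col in ("start", "end", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed line {lineno} (column {col!r})")
        raw[col] = vals.astype(np.int64)
    if ((raw["n_meth"] < 0) | (raw["n_unmeth"] < 0)).any():
        lineno = int(np.flatnonzero(((raw["n_meth"] < 0) | (raw["n_unmeth"] < 0)).to_numpy())[0]) + 1
        raise ValueError(f"{path}: negative count at line {lineno}")
    df = pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": raw["start"] - 1,  # 1-based inclusive -> 0-based
        "n_meth": raw["n_meth"],
        "n_unmeth": raw["n_unmeth"],
    })
    if len(df) and not df[["chrom", "pos"]].apply(tuple, axis=1).is_monotonic_increasing:
        warnings.warn(f"{path}: unsorted coverage file; sorting", stacklevel=2)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return MethylomeTrack(sample_id, df)


def write_coverage_file(track: MethylomeTrack, path) -> None:
    """Write a track as a Bismark-style coverage file (1-based inclusive)."""
    df = track.df
    cov = (df["n_meth"] + df["n_unmeth"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * df["n_meth"].to_numpy(float) / np.where(cov > 0, cov, 1), 0.0)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"] + 1,
        "end": df["pos"] + 1,
        "pct": np.round(pct, 6),
        "n_meth": df["n_meth"],
        "n_unmeth": df["n_unmeth"],
    })
    out.to_csv(str(path), sep="\t", header=False, index=False, compression="infer")


def write_regions_bed(regions: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    """Write a region table as BED6+ (0-based half-open).

    ``regions`` needs ``chrom, start, end``; ``name``/``score``/``strand``
    are filled with BED placeholders when absent, then any ``extra_cols``
    are appended.
    """
    bed = pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"].astype(np.int64),
        "end": regions["end"].astype(np.int64),
        "name": regions["name"] if "name" in regions else ".",
        "score": regions["score"] if "score" in regions else 0,
        "strand": regions["strand"] if "strand" in regions else ".",
    })
    for col in extra_cols or []:
        bed[col] = regions[col].to_numpy()
    bed.to_csv(str(path), sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a region DataFrame (extra columns kept)."""
    base = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=base[:3])
    ncol = df.shape[1]
    names = base[:ncol] + [f"col{i}" for i in range(len(base), ncol)]
    df.columns = names[:ncol]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def region_mean_beta(
    track: MethylomeTrack,
    region: GenomicRegion,
    min_coverage: int = 1,
    weighted: bool = False,
) -> float:
    """Mean beta over CpGs inside ``region`` with coverage >= min_coverage.

    Unweighted across CpGs by default (each qualifying CpG contributes
    equally, matching array-style beta averaging); ``weighted=True`` weights
    by coverage instead.  Returns NaN when no CpG qualifies.
    """
    sub = track.chrom_data(region.chrom)
    pos = sub["pos"].to_numpy()
    lo, hi = np.searchsorted(pos, [region.start, region.end])
    if hi <= lo:
        return math.nan
    m = sub["n_meth"].to_numpy(float)[lo:hi]
    u = sub["n_unmeth"].to_numpy(float)[lo:hi]
    cov = m + u
    keep = cov >= max(min_coverage, 1)
    if not keep.any():
        return math.nan
    if weighted:
        return float(m[keep].sum() / cov[keep].sum())
    return float(np.mean(m[keep] / cov[keep]))


def region_mean_betas(
    track: MethylomeTrack, regions: pd.DataFrame, min_coverage: int = 1
) -> np.ndarray:
    """Vectorized :func:`region_mean_beta` over a region table."""
    out = np.full(len(regions), np.nan)
    for i, row in enumerate(regions.itertuples(index=False)):
        out[i] = region_mean_beta(
            track, GenomicRegion(row.chrom, int(row.start), int(row.end)),
            min_coverage=min_coverage,
        )
    return out


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class RegionAnnotation:
    """CpG-context and gene-proximity labels for one region.

    ``cpg_context`` uses the community-standard distances: island = >=1 bp
    overlap with an annotated island, shore = within 2 kb of an island edge,
    shelf = 2-4 kb, open sea beyond 4 kb.  ``gene_relation`` is the three-way
    genic / promoter (within 2 kb of a TSS) / intergenic split.
    """

    cpg_context: str | None
    gene_relation: str | None
    nearest_gene: str | None = None
    distance_to_gene: int | None = None


SHORE_BP = 2000
SHELF_BP = 4000
PROMOTER_BP = 2000


def _interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, start_b - end_a, start_a - end_b)


def _nearest_gap(region: GenomicRegion, others: pd.DataFrame) -> int | None:
    sub = others[others["chrom"] == region.chrom]
    if sub.empty:
        return None
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    gaps = np.maximum(0, np.maximum(starts - region.end, region.start - ends))
    return int(gaps.min())


def annotate_region(
    region: GenomicRegion,
    islands: pd.DataFrame | None,
    genes: pd.DataFrame | None = None,
) -> RegionAnnotation:
    """Assign CpG context and gene relation to one region.

    ``islands`` and ``genes`` are region DataFrames (``chrom,start,end`` plus
    optional ``name``/``strand`` for genes).  A missing annotation set yields
    ``None`` for the corresponding label rather than a default category.
    Context ties resolve island > shore > shelf.
    """
    context = None
    if islands is not None and len(islands):
        gap = _nearest_gap(region, islands)
        if gap is None:
            context = "open_sea"
        elif gap == 0:
            context = "island"
        elif gap <= SHORE_BP:
            context = "shore"
        elif gap <= SHELF_BP:
            context = "shelf"
        else:
            context = "open_sea"

    relation = None
    nearest_gene = None
    dist_gene = None
    if genes is not None and len(genes):
        sub = genes[genes["chrom"] == region.chrom]
        if sub.empty:
            relation = "intergenic"
        else:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            gaps = np.maximum(0, np.maximum(starts - region.end, region.start - ends))
            # TSS = start for + strand (or unstranded), end for - strand
            if "strand" in sub:
                strands = sub["strand"].to_numpy()
                tss = np.where(strands == "-", ends, starts)
            else:
                tss = starts
            tss_dist = np.maximum(0, np.maximum(tss - region.end + 1, region.start - tss))
            if (gaps == 0).any():
                relation = "genic"
            elif (tss_dist <= PROMOTER_BP).any():
                relation = "promoter_2kb"
            else:
                relation = "intergenic"
            mid = region.midpoint
            gene_mid = 0.5 * (starts + ends)
            j = int(np.argmin(np.abs(gene_mid - mid)))
            nearest_gene = str(sub.iloc[j]["name"]) if "name" in sub else None
            dist_gene = int(gaps[j])
    return RegionAnnotation(context, relation, nearest_gene, dist_gene)


def annotate_regions(
    regions: pd.DataFrame,
    islands: pd.DataFrame | None,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate a region table; returns it with annotation columns appended."""
    anns = [
        annotate_region(GenomicRegion(r.chrom, int(r.start), int(r.end)), islands, genes)
        for r in regions.itertuples(index=False)
    ]
    out = regions.copy()
    out["cpg_context"] = [a.cpg_context for a in anns]
    out["gene_relation"] = [a.gene_relation for a in anns]
    out["nearest_gene"] = [a.nearest_gene for a in anns]
    out["distance_to_gene"] = [a.distance_to_gene for a in anns]
    return out


def interval_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-level Jaccard index between two region sets.

    Regions within each set are unioned first; the index is
    ``|A n B| / |A u B|`` in base pairs (NaN when both are empty).
    """
    def to_union(df: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            ivs = sorted(zip(sub["start"].astype(int), sub["end"].astype(int)))
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out[str(chrom)] = merged
        return out

    ua, ub = to_union(a), to_union(b)
    inter = 0
    total_a = sum(e - s for ivs in ua.values() for s, e in ivs)
    total_b = sum(e - s for ivs in ub.values() for s, e in ivs)
    for chrom in set(ua) & set(ub):
        for s1, e1 in ua[chrom]:
            for s2, e2 in ub[chrom]:
                inter += max(0, min(e1, e2) - max(s1, s2))
    union = total_a + total_b - inter
    if union == 0:
        return math.nan
    return inter / union
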