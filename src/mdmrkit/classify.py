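"""Region-beta feature matrices and tumor/normal random-forest evaluation.

The feature matrix is regions x samples of region mean beta values.
Performance is estimated with repeated (default 10x) stratified 3-fold
cross-validation of a random forest (500 trees); out-of-fold scores are
pooled across all repeats into a single ROC and AUC, with a bootstrap
confidence interval.  Missing betas are imputed with the training fold's
per-region median, so no test information leaks into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

from .methio import MethylomeTrack, region_mean_betas

N_TREES = 500
POSITIVE_CLASS = "tumor"


@dataclass
class RegionBetaMatrix:
    """Mean beta per (region, sample) plus class labels.

    ``values``: DataFrame indexed by region id (``chrom:start-end``) with
    one column per sample; entries in [0, 1] or NaN.  ``labels``: Series
    mapping sample id to {tumor, normal}.  ``regions``: the region table.
    """

    values: pd.DataFrame
    labels: pd.Series
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("region and sample identifiers must be unique")
        v = self.values.to_numpy(float)
        finite = v[np.isfinite(v)]
        if len(finite) and ((finite < 0) | (finite > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")


def region_ids(regions: pd.DataFrame) -> pd.Index:
    return pd.Index([f"{c}:{s}-{e}" for c, s, e in
                     zip(regions["chrom"], regions["start"], regions["end"])])


def build_matrix(
    tracks: list[MethylomeTrack],
    regions: pd.DataFrame,
    labels: pd.Series | dict[str, str] | None = None,
    min_coverage: int = 5,
) -> RegionBetaMatrix:
    """Region x sample mean-beta matrix via :func:`region_mean_beta`.

    Missing values (no qualifying CpG) are recorded as NaN, not imputed.
    ``labels`` maps sample ids to tumor/normal; samples without a label
    default to "unknown".
    """
    if regions is None or len(regions) == 0:
        raise ValueError("region set is empty")
    regions = regions.reset_index(drop=True)
    cols = {}
    for t in tracks:
        cols[t.sample_id] = region_mean_betas(t, regions, min_coverage=min_coverage)
    values = pd.DataFrame(cols, index=region_ids(regions))
    if labels is None:
        labels = {}
    lab = pd.Series({t.sample_id: dict(labels).get(t.sample_id, "unknown") for t in tracks})
    return RegionBetaMatrix(values, lab, regions)


@dataclass
class CVResult:
    """Pooled repeated-CV output of the tumor/normal classifier."""

    fold_scores: pd.DataFrame  # repeat, fold, sample_id, score, truth
    auc: float
    auc_ci: tuple[float, float]
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    per_fold_auc: pd.DataFrame  # repeat, fold, auc
    final_model: RandomForestClassifier
    train_medians: pd.Series
    region_index: pd.Index
    seed: int
    n_regions_used: int = 0

    def __post_init__(self) -> None:
        if self.n_regions_used == 0:
            self.n_regions_used = len(self.region_index)


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    nan = np.isnan(X)
    X[nan] = np.take(medians, np.nonzero(nan)[1])
    return X


def _fit_rf(X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(n_estimators=N_TREES, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def cross_validate(
    matrix: RegionBetaMatrix,
    n_repeats: int = 10,
    n_folds: int = 3,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> CVResult:
    """Repeated stratified k-fold CV of the tumor/normal random forest.

    Folds are stratified by class and reproducible from the seed.  Each
    training fold imputes missing betas with its own per-region medians
    (features unobserved in the fold fall back to 0.5).  Out-of-fold
    tumor-probability scores are pooled across all repeats into one ROC;
    the AUC confidence interval is a percentile bootstrap over the pooled
    score/truth pairs.
    """
    y_all = matrix.labels.reindex(matrix.values.columns)
    classes = set(y_all.unique())
    if len(classes) < 2:
        raise ValueError("cross-validation needs two classes (tumor and normal)")
    X_all = matrix.values.to_numpy(float).T  # samples x regions
    y = (y_all == POSITIVE_CLASS).to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} samples per class for {n_folds}-fold CV")

    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    rows = []
    fold_auc = []
    for split_i, (tr, te) in enumerate(cv.split(X_all, y)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN regions
            med = np.nanmedian(X_all[tr], axis=0)
        med = np.nan_to_num(med, nan=0.5)
        rf = _fit_rf(_impute(X_all[tr], med), y[tr],
                     seed=(seed * 1_000 + split_i) % (2**31))
        scores = rf.predict_proba(_impute(X_all[te], med))[:, list(rf.classes_).index(1)]
        repeat, fold = divmod(split_i, n_folds)
        for j, s in zip(te, scores):
            rows.append({"repeat": repeat, "fold": fold,
                         "sample_id": matrix.values.columns[j],
                         "score": float(s), "truth": int(y[j])})
        if len(np.unique(y[te])) == 2:
            fold_auc.append({"repeat": repeat, "fold": fold,
                             "auc": float(roc_auc_score(y[te], scores))})
    fold_scores = pd.DataFrame(rows)
    pooled_y = fold_scores["truth"].to_numpy()
    pooled_s = fold_scores["score"].to_numpy()
    auc = float(roc_auc_score(pooled_y, pooled_s))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(pooled_y), len(pooled_y))
        if len(np.unique(pooled_y[idx])) == 2:
            boots.append(roc_auc_score(pooled_y[idx], pooled_s[idx]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    fpr, tpr, thr = roc_curve(pooled_y, pooled_s)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full_med = np.nan_to_num(np.nanmedian(X_all, axis=0), nan=0.5)
    final = _fit_rf(_impute(X_all, full_med), y, seed=seed)
    return CVResult(fold_scores, auc, ci, roc_points,
                    pd.DataFrame(fold_auc), final,
                    pd.Series(full_med, index=matrix.values.index),
                    matrix.values.index, seed)


def _positional_intersection(regions: pd.DataFrame, subset: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``regions`` rows overlapping any subset region."""
    mask = np.zeros(len(regions), bool)
    for chrom, sub in subset.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        here = regions["chrom"].to_numpy() == chrom
        for i in np.flatnonzero(here):
            s, e = regions["start"].iloc[i], regions["end"].iloc[i]
            if ((starts < e) & (s < ends)).any():
                mask[i] = True
    return mask


def subset_and_apply(
    matrix: RegionBetaMatrix,
    region_subset: pd.DataFrame,
    n_repeats: int = 10,
    n_folds: int = 3,
    seed: int = 0,
) -> CVResult:
    """Re-evaluate the classifier on the regions intersecting a panel.

    Emulates restricting a WGBS-derived region set to an external probe
    panel: matrix regions with >= 1 bp positional intersection with
    ``region_subset`` are kept and the forest is retrained and
    cross-validated on that reduced set.  ``n_regions_used`` is reported;
    an empty intersection is an error.
    """
    mask = _positional_intersection(matrix.regions, region_subset)
    if not mask.any():
        raise ValueError("region subset does not intersect the matrix regions")
    sub = RegionBetaMatrix(matrix.values.loc[mask], matrix.labels,
                           matrix.regions.loc[mask].reset_index(drop=True))
    res = cross_validate(sub, n_repeats=n_repeats, n_folds=n_folds, seed=seed)
    res.n_regions_used = int(mask.sum())
    return res
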