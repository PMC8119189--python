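"""Per-subject morphometric signatures and patient classification.

The signature condenses all glomeruli of one subject into 25 features:
{min, max, mean, median, variance} of five podometric measures
(podocyte number, podocyte density, closest-neighbor distance, nuclear
profile area, glomerular profile area). Classification is a logistic
regression evaluated with leave-one-out cross-validation: for every
subject the scaler and the model are fitted on all other subjects only,
and the pooled out-of-fold probabilities give ROC/PR curves. A
Pareto-scaled PCA of single glomeruli and the adapted-disease-score /
podocyte-size-range ratio complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .evaluation import curve_sweep

__all__ = [
    "SubjectSignature", "ClassificationResult", "MEASURES", "STATS",
    "subject_signature", "signature_frame", "ZScaler", "loo_classify",
    "pca_glomeruli", "adapted_score_ratio",
]

MEASURES = ("number", "density", "distance", "nuclear_area", "glom_area")
STATS = ("min", "max", "mean", "median", "variance")

_COLUMN_OF = dict(number="podocyte_number_est",
                  density="podocyte_density_per_1e6um3",
                  distance="median_neighbor_distance_um",
                  nuclear_area="mean_nuclear_area_um2",
                  glom_area="glom_area_um2")


@dataclass
class SubjectSignature:
    subject_id: str
    group: str
    features: dict                       # name -> float (NaN = missing)
    n_glomeruli: int
    metadata: dict = field(default_factory=dict)

    def vector(self, names=None) -> np.ndarray:
        names = names or feature_names()
        return np.array([self.features[n] for n in names], dtype=float)


def feature_names() -> list:
    return [f"{m}_{s}" for m in MEASURES for s in STATS]


def subject_signature(records, group: str = "",
                      metadata: dict | None = None) -> SubjectSignature:
    """Build the 25-feature signature from one subject's GlomRecords.

    Per-glomerulus neighbor distances are first summarized by their
    median; variances use the n-1 denominator and are NaN (missing) for
    subjects with a single glomerulus.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one glomerulus record")
    values = {m: [] for m in MEASURES}
    for r in records:
        values["number"].append(r.podocyte_number_est)
        values["density"].append(r.podocyte_density_per_1e6um3)
        values["distance"].append(r.median_neighbor_distance_um)
        values["nuclear_area"].append(r.mean_nuclear_area_um2)
        values["glom_area"].append(r.glom_area_um2)
    feats = {}
    for m, vals in values.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            v = np.array([np.nan])
        feats[f"{m}_min"] = float(np.nanmin(v))
        feats[f"{m}_max"] = float(np.nanmax(v))
        feats[f"{m}_mean"] = float(np.nanmean(v))
        feats[f"{m}_median"] = float(np.nanmedian(v))
        feats[f"{m}_variance"] = float(np.var(v, ddof=1)) if len(v) >= 2 \
            else np.nan
    return SubjectSignature(records[0].subject_id, group, feats,
                            len(records), metadata or {})


def signature_frame(glom_frame: pd.DataFrame,
                    meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signatures for every subject in a per-glomerulus podometrics table.

    Expects the columns written by stereology.records_to_frame; `meta`
    (subject_id, group, optional age/sex/egfr) is merged when given.
    """
    rows = []
    for sid, sub in glom_frame.groupby("subject_id"):
        feats = {}
        for m in MEASURES:
            v = sub[_COLUMN_OF[m]].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) == 0:
                v = np.array([np.nan])
            feats[f"{m}_min"] = np.nanmin(v)
            feats[f"{m}_max"] = np.nanmax(v)
            feats[f"{m}_mean"] = np.nanmean(v)
            feats[f"{m}_median"] = np.nanmedian(v)
            feats[f"{m}_variance"] = np.var(v, ddof=1) if len(v) >= 2 \
                else np.nan
        feats["subject_id"] = sid
        feats["n_glomeruli"] = len(sub)
        rows.append(feats)
    out = pd.DataFrame(rows)
    if meta is not None:
        out = out.merge(meta, on="subject_id", how="left")
    return out


# ----------------------------------------------------------------------
class ZScaler:
    """Column z-normalization fitted on training subjects only; columns
    with zero spread are centered but not scaled."""

    def __init__(self):
        self.mean_ = None
        self.sd_ = None

    def fit(self, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least two training subjects")
        self.mean_ = np.nanmean(X, axis=0)
        self.sd_ = np.nanstd(X, axis=0, ddof=1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        return (np.asarray(X, dtype=float) - self.mean_) / sd


@dataclass
class ClassificationResult:
    subject_ids: list
    y_true: np.ndarray
    oof_prob: np.ndarray                # one out-of-fold prob per subject
    auc_roc: float
    auc_pr: float
    roc: np.ndarray
    pr: np.ndarray
    confusion: dict                     # tn/fp/fn/tp at 0.5
    accuracy: float
    fold_coefs: np.ndarray = None       # (n_subjects, n_features + 1)


FEATURE_SUBSETS = {
    "signature_25": None,               # all 25, resolved at call time
    "combined_score_3": ["number_median", "density_median",
                         "nuclear_area_median"],
    "egfr_only": ["egfr"],
}


def loo_classify(signatures: pd.DataFrame, feature_subset="signature_25",
                 label_column: str = "group", positive: str = "disease",
                 ridge_inverse_strength: float = 100.0,
                 seed: int = 0) -> ClassificationResult:
    """Leave-one-out logistic regression over subjects.

    Every fold fits the z-scaler, the median imputation of missing
    variance features and the (weakly ridge-penalized) logistic model on
    the n-1 training subjects, then scores the held-out subject; results
    pool the n out-of-fold probabilities.
    """
    if isinstance(feature_subset, str):
        cols = FEATURE_SUBSETS.get(feature_subset, "missing")
        if cols == "missing":
            raise ValueError(f"unknown feature subset {feature_subset!r}")
        cols = cols or feature_names()
    else:
        cols = list(feature_subset)
    missing = set(cols) - set(signatures.columns)
    if missing:
        raise ValueError(f"signature table lacks columns {sorted(missing)}")
    y = (signatures[label_column] == positive).to_numpy(dtype=int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two subjects per group")
    X = signatures[cols].to_numpy(dtype=float)
    n = len(signatures)
    oof = np.zeros(n)
    fold_coefs = np.zeros((n, len(cols) + 1))
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, Xte = X[tr].copy(), X[[i]].copy()
        med = np.nanmedian(Xtr, axis=0)
        for arr in (Xtr, Xte):
            nanmask = ~np.isfinite(arr)
            arr[nanmask] = np.broadcast_to(med, arr.shape)[nanmask]
        scaler = ZScaler().fit(Xtr)
        clf = LogisticRegression(C=ridge_inverse_strength, solver="lbfgs",
                                 max_iter=2000, random_state=seed)
        clf.fit(scaler.transform(Xtr), y[tr])
        oof[i] = clf.predict_proba(scaler.transform(Xte))[0, 1]
        fold_coefs[i] = np.append(clf.coef_[0], clf.intercept_[0])
    res = curve_sweep(y, oof)
    pred = (oof >= 0.5).astype(int)
    conf = dict(tn=int(((pred == 0) & (y == 0)).sum()),
                fp=int(((pred == 1) & (y == 0)).sum()),
                fn=int(((pred == 0) & (y == 1)).sum()),
                tp=int(((pred == 1) & (y == 1)).sum()))
    return ClassificationResult(
        list(signatures["subject_id"]), y, oof,
        res["auc_roc"], res["auc_pr"], res["roc"], res["pr"], conf,
        float((pred == y).mean()), fold_coefs)


def pca_glomeruli(glom_frame: pd.DataFrame, n_components: int = 2,
                  measures=MEASURES):
    """PCA of single glomeruli after Pareto scaling (divide each centered
    feature by the square root of its standard deviation).

    Returns (scores DataFrame, explained variance ratios).
    """
    cols = [_COLUMN_OF[m] for m in measures]
    X = glom_frame[cols].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    X = X[keep]
    if len(X) < 3:
        raise ValueError("need at least three complete glomeruli")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValueError("constant feature matrix")
    Xp = (X - X.mean(axis=0)) / np.sqrt(np.where(sd > 0, sd, 1.0))
    n_components = min(n_components, Xp.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xp)
    out = glom_frame.loc[keep, ["subject_id", "glomerulus_id"]].copy() \
        if {"subject_id", "glomerulus_id"} <= set(glom_frame.columns) \
        else pd.DataFrame(index=np.flatnonzero(keep))
    for k in range(n_components):
        out[f"pc{k + 1}"] = scores[:, k]
    return out, pca.explained_variance_ratio_


def adapted_score_ratio(anca_score: float, records_or_sizes) -> float:
    """Clinical-score / podocyte-size-range ratio for one subject.

    The size range is max/min of the per-glomerulus mean nuclear profile
    area; a larger within-biopsy size spread lowers the ratio.
    """
    sizes = []
    for r in records_or_sizes:
        sizes.append(r.mean_nuclear_area_um2 if hasattr(
            r, "mean_nuclear_area_um2") else float(r))
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[np.isfinite(sizes)]
    if len(sizes) < 2:
        raise ValueError("need at least two glomeruli for a size range")
    if sizes.min() <= 0:
        raise ValueError("nonpositive podocyte size")
    rng_ratio = sizes.max() / sizes.min()
    return float(anca_score) / rng_ratio
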