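"""Model-comparison protocol for ISS prediction.

Pipeline: z-score standardization of continuous features, Borderline-SMOTE
oversampling of the minority class, recursive feature elimination (RFE),
an 80/20 stratified split, per-model 10-fold cross-validated grid search,
and AUC/accuracy/sensitivity/specificity reporting on the held-out test
split.

Two SMOTE placements are supported: ``"train_only"`` (default; synthetic
samples are built exclusively from training rows, so the test set stays
untouched) and ``"before_split"`` (oversample the full dataset before
splitting, replicating protocols that preprocess first - this leaks
minority-class information into the test set and typically inflates test
metrics; it is provided to reproduce such protocols, not to endorse them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = [
    "Standardizer",
    "BorderlineSmote",
    "borderline_smote",
    "rfe",
    "BenchmarkConfig",
    "ModelReport",
    "default_models",
    "run_benchmark",
    "ISS_PREDICTOR_PRESET",
]

#: the six predictors reported as the RFE-selected ISS set, as a named
#: preset for synthetic experiments
ISS_PREDICTOR_PRESET = [
    "height",
    "dm",
    "max_curvature",
    "aneurysm_neck",
    "hypertension",
    "hyperlipidemia",
]


class Standardizer:
    """Z-score transform (population SD) fitted on one partition only.

    Binary 0/1 columns pass through untouched; continuous columns are
    centered and scaled with the mean/SD learned in :meth:`fit`.  Columns
    with zero SD on the fitting partition are dropped with a warning.
    """

    def __init__(self) -> None:
        self.columns_: Optional[list[str]] = None
        self.means_: Optional[pd.Series] = None
        self.sds_: Optional[pd.Series] = None
        self.dropped_: list[str] = []

    @staticmethod
    def _continuous(X: pd.DataFrame) -> list[str]:
        return [
            c
            for c in X.columns
            if not set(pd.unique(X[c].dropna())) <= {0, 1, 0.0, 1.0}
        ]

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        cont = self._continuous(X)
        means = X[cont].mean()
        sds = X[cont].std(ddof=0)
        self.dropped_ = [c for c in cont if sds[c] == 0.0]
        if self.dropped_:
            warnings.warn(
                f"dropping zero-variance columns: {self.dropped_}", RuntimeWarning
            )
        self.columns_ = [c for c in cont if c not in self.dropped_]
        self.means_ = means[self.columns_]
        self.sds_ = sds[self.columns_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("Standardizer is not fitted")
        out = X.drop(columns=[c for c in self.dropped_ if c in X.columns]).copy()
        out[self.columns_] = (X[self.columns_] - self.means_) / self.sds_
        return out

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


class BorderlineSmote:
    """Borderline-SMOTE (variant 1) oversampling to exact class balance.

    A minority point is *in danger* when m' of its k nearest neighbors
    (over both classes) belong to the majority class with k/2 <= m' < k;
    points with m' = k are treated as noise and never seed synthesis.
    Synthetic points are drawn uniformly on segments from danger points to
    their nearest minority-class neighbors.
    """

    def __init__(self, k: int = 5, random_state: Optional[int] = None) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.random_state = random_state
        #: (danger_index, minority_neighbor_index) per synthetic row, in the
        #: indexing of the input arrays
        self.parents_: list[tuple[int, int]] = []

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("y must be binary")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        self.parents_ = []
        if n_min == n_maj:
            return X.copy(), y.copy()
        if n_min < self.k + 1:
            raise ValueError(
                f"minority class has {n_min} members; Borderline-SMOTE with "
                f"k={self.k} needs at least k+1={self.k + 1}"
            )
        rng = np.random.default_rng(self.random_state)
        min_idx = np.flatnonzero(y == minority)
        # danger assessment over the full sample
        nn_all = NearestNeighbors(n_neighbors=self.k + 1).fit(X)
        _, neigh = nn_all.kneighbors(X[min_idx])
        neigh = neigh[:, 1:]  # drop self
        m_prime = (y[neigh] != minority).sum(axis=1)
        danger = min_idx[(m_prime >= self.k / 2.0) & (m_prime < self.k)]
        if len(danger) == 0:
            warnings.warn(
                "no borderline minority samples found; returning data unchanged",
                RuntimeWarning,
            )
            return X.copy(), y.copy()
        # minority-only neighbor structure for synthesis
        k_syn = min(self.k, n_min - 1)
        nn_min = NearestNeighbors(n_neighbors=k_syn + 1).fit(X[min_idx])
        _, neigh_min = nn_min.kneighbors(X[danger])
        need = n_maj - n_min
        seeds = danger[rng.integers(0, len(danger), size=need)]
        new_rows = np.empty((need, X.shape[1]))
        for i, s in enumerate(seeds):
            row = np.flatnonzero(danger == s)[0]
            options = neigh_min[row]
            options = options[min_idx[options] != s]
            q = min_idx[options[rng.integers(0, len(options))]]
            u = rng.uniform()
            new_rows[i] = X[s] + u * (X[q] - X[s])
            self.parents_.append((int(s), int(q)))
        X_out = np.vstack([X, new_rows])
        y_out = np.concatenate([y, np.full(need, minority, dtype=int)])
        return X_out, y_out


def borderline_smote(X, y, k: int = 5, seed: Optional[int] = None):
    """Functional wrapper over :class:`BorderlineSmote`."""
    sampler = BorderlineSmote(k=k, random_state=seed)
    Xr, yr = sampler.fit_resample(X, y)
    return Xr, yr, sampler.parents_


def rfe(model, X: pd.DataFrame, y, n_target: int) -> list[str]:
    """Recursive feature elimination down to ``n_target`` features.

    Refits ``model`` after each drop; importance is |coefficient| for
    linear models, ``feature_importances_`` otherwise.  Ties drop the
    later column, so of two duplicated columns the earlier one survives.
    """
    cols = list(X.columns)
    if n_target >= len(cols):
        if n_target > len(cols):
            warnings.warn("n_target exceeds feature count; keeping all", RuntimeWarning)
        return cols
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    X = X.copy()
    y = np.asarray(y)
    while len(cols) > n_target:
        est = clone(model)
        est.fit(X[cols].to_numpy(), y)
        if hasattr(est, "coef_"):
            imp = np.abs(np.ravel(est.coef_))
        elif hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_)
        else:
            raise ValueError("model exposes neither coef_ nor feature_importances_")
        worst = max(np.flatnonzero(imp == imp.min()))
        cols.pop(int(worst))
    return cols


@dataclass(frozen=True)
class BenchmarkConfig:
    """Protocol parameters for :func:`run_benchmark`."""

    test_fraction: float = 0.2
    cv_folds: int = 10
    smote_k: int = 5
    smote_placement: str = "train_only"  # or "before_split"
    rfe_n_features: int = 6
    models: Optional[Mapping[str, tuple]] = None  # name -> (estimator, grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction <= 0.5:
            raise ValueError("test_fraction must lie in (0, 0.5]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.smote_placement not in ("train_only", "before_split"):
            raise ValueError("smote_placement must be 'train_only' or 'before_split'")


@dataclass(frozen=True)
class ModelReport:
    model: str
    cv_auc_mean: float
    cv_auc_lo: float
    cv_auc_hi: float
    val_auc: float
    test_auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    selected_features: tuple = ()
    best_params: tuple = ()

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_lo": self.cv_auc_lo,
            "cv_auc_hi": self.cv_auc_hi,
            "val_auc": self.val_auc,
            "test_auc": self.test_auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def default_models(seed: int = 0) -> dict[str, tuple]:
    """Classifier families with small, explicit hyperparameter grids."""
    import xgboost as xgb

    return {
        "logistic": (
            LogisticRegression(max_iter=5000),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "elastic_net": (
            LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=20000, random_state=seed
            ),
            {"C": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]},
        ),
        "svm": (
            SVC(kernel="rbf", random_state=seed),
            {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
        ),
        "random_forest": (
            RandomForestClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [2, 4, None]},
        ),
        "xgboost": (
            xgb.XGBClassifier(
                n_estimators=100,
                tree_method="hist",
                n_jobs=1,
                random_state=seed,
                eval_metric="logloss",
            ),
            {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
        ),
    }


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def _t_interval(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(values))
    if len(values) < 2:
        return m, m, m
    half = stats.t.ppf(0.975, len(values) - 1) * np.std(values, ddof=1) / np.sqrt(len(values))
    return m, m - float(half), m + float(half)


def run_benchmark(
    cohort: pd.DataFrame,
    config: BenchmarkConfig,
    outcome: str = "iss",
    features: Optional[Sequence[str]] = None,
) -> tuple[list[ModelReport], dict]:
    """Run the full benchmarking protocol; returns reports + provenance.

    Provenance records the seed, the SMOTE placement and parent indices,
    the RFE-selected features and each model's grid winner, enough to audit
    that no synthetic sample was built from test rows under "train_only".
    """
    if features is None:
        features = [c for c in cohort.columns if c not in ("iss", "co")]
    models = dict(config.models) if config.models is not None else default_models(config.seed)
    if len(models) < 2:
        raise ValueError("need at least 2 model specs to compare")
    X = cohort[list(features)].reset_index(drop=True)
    y = cohort[outcome].to_numpy(dtype=int)

    seed = config.seed
    sampler = BorderlineSmote(k=config.smote_k, random_state=seed)
    if config.smote_placement == "before_split":
        scaler = Standardizer().fit(X)
        Xs = scaler.transform(X)
        X_res, y_res = sampler.fit_resample(Xs.to_numpy(), y)
        X_res = pd.DataFrame(X_res, columns=Xs.columns)
        tr_idx, te_idx = train_test_split(
            np.arange(len(y_res)),
            test_size=config.test_fraction,
            stratify=y_res,
            random_state=seed,
        )
        X_tr, y_tr = X_res.iloc[tr_idx], y_res[tr_idx]
        X_te, y_te = X_res.iloc[te_idx], y_res[te_idx]
        smote_parent_rows = [p for pair in sampler.parents_ for p in pair]
    else:
        tr_idx, te_idx = train_test_split(
            np.arange(len(y)),
            test_size=config.test_fraction,
            stratify=y,
            random_state=seed,
        )
        scaler = Standardizer().fit(X.iloc[tr_idx])
        X_tr_raw = scaler.transform(X.iloc[tr_idx]).reset_index(drop=True)
        X_te = scaler.transform(X.iloc[te_idx]).reset_index(drop=True)
        y_te = y[te_idx]
        res_X, y_tr = sampler.fit_resample(X_tr_raw.to_numpy(), y[tr_idx])
        X_tr = pd.DataFrame(res_X, columns=X_tr_raw.columns)
        # parents are positions within the training partition; map to cohort rows
        smote_parent_rows = [int(tr_idx[p]) for pair in sampler.parents_ for p in pair]

    selector = LogisticRegression(max_iter=5000)
    selected = rfe(selector, X_tr, y_tr, min(config.rfe_n_features, X_tr.shape[1]))
    Xtr = X_tr[selected].to_numpy()
    Xte = X_te[selected].to_numpy()

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    fold_counts = np.bincount(y_tr)
    if fold_counts.min() < config.cv_folds:
        raise ValueError(
            "too few minority samples for stratified "
            f"{config.cv_folds}-fold cross-validation"
        )
    reports = []
    provenance: dict = {
        "seed": seed,
        "smote_placement": config.smote_placement,
        "smote_parent_rows": smote_parent_rows,
        "test_rows": [int(i) for i in te_idx] if config.smote_placement == "train_only" else None,
        "selected_features": list(selected),
        "models": {},
    }
    for name, (est, grid) in models.items():
        gs = GridSearchCV(
            est,
            grid,
            scoring="roc_auc",
            cv=cv,
            refit=True,
            return_train_score=True,
            n_jobs=1,
        )
        gs.fit(Xtr, y_tr)
        b = gs.best_index_
        train_fold_aucs = np.array(
            [gs.cv_results_[f"split{i}_train_score"][b] for i in range(config.cv_folds)]
        )
        val_fold_aucs = np.array(
            [gs.cv_results_[f"split{i}_test_score"][b] for i in range(config.cv_folds)]
        )
        cv_mean, cv_lo, cv_hi = _t_interval(train_fold_aucs)
        best = gs.best_estimator_
        s_te = _scores(best, Xte)
        pred = best.predict(Xte)
        tp = int(np.sum((pred == 1) & (y_te == 1)))
        tn = int(np.sum((pred == 0) & (y_te == 0)))
        reports.append(
            ModelReport(
                model=name,
                cv_auc_mean=cv_mean,
                cv_auc_lo=cv_lo,
                cv_auc_hi=cv_hi,
                val_auc=float(np.mean(val_fold_aucs)),
                test_auc=float(roc_auc_score(y_te, s_te)),
                accuracy=float(np.mean(pred == y_te)),
                sensitivity=tp / max(int(np.sum(y_te == 1)), 1),
                specificity=tn / max(int(np.sum(y_te == 0)), 1),
                selected_features=tuple(selected),
                best_params=tuple(sorted(gs.best_params_.items())),
            )
        )
        provenance["models"][name] = {"best_params": dict(gs.best_params_)}
    return reports, provenance
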