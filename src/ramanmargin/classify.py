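"""Patient-grouped SVM classification and ROC reporting.

Four binary dichotomies are supported: cancer vs normal+fat ("A"), cancer
vs normal ("B"), cancer vs fat ("C"), and fat vs the rest ("FAT", the
fat-detection model used for the label-consistency screen). Each model is a
class-weighted linear SVM whose hyperparameters — the regularization
parameter C in [1e-3, 1] and the minority-class cost multiplier gamma — are
chosen by grid search under five-fold cross-validation grouped by patient,
so measurements from one patient never appear on both sides of a split.
Held-out decision values are mapped to posterior probabilities by a
Platt-style sigmoid fitted on the training folds, pooled across folds, and
swept against a threshold lambda to trace the ROC curve. The reported
operating point is the curve point closest to the ideal top-left corner.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix, l1_rank_features
from .spectra import RawAcquisition

__all__ = [
    "MODEL_DICHOTOMIES",
    "ModelSpec",
    "TrainedModel",
    "ROCResult",
    "make_grouped_folds",
    "train_weighted_svm",
    "grid_search_cv",
    "roc_curve",
    "operating_point",
    "run_model",
    "accumulation_study",
]

#: model id -> (positive class, negative classes)
MODEL_DICHOTOMIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "A": ("cancer", ("normal", "fat")),
    "B": ("cancer", ("normal",)),
    "C": ("cancer", ("fat",)),
    "FAT": ("fat", ("cancer", "normal")),
}


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameter search space and CV layout for one binary model."""

    model_id: str = "A"
    c_grid: tuple[float, ...] = tuple(np.logspace(-3, 0, 7))
    gamma_grid: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    n_folds: int = 5
    max_features: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_DICHOTOMIES:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(not (1e-3 - 1e-12 <= c <= 1.0 + 1e-12) for c in self.c_grid):
            raise ValueError("C grid values must lie within [1e-3, 1]")


def make_grouped_folds(patient_ids: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per measurement, with all of a patient's measurements in one fold."""
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    if patients.size < k:
        raise ValueError(f"need at least {k} patients for {k}-fold grouped CV, got {patients.size}")
    rng = np.random.default_rng(seed)
    shuffled = patients[rng.permutation(patients.size)]
    fold_of_patient = {p: i % k for i, p in enumerate(shuffled)}
    return np.array([fold_of_patient[p] for p in patient_ids])


@dataclass(eq=False)
class TrainedModel:
    """Linear decision function plus a monotone sigmoid posterior map."""

    weights: np.ndarray
    bias: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    platt_slope: float
    platt_intercept: float
    C: float
    gamma: float
    positive_class: int = 1

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Xs @ self.weights + self.bias

    def posterior(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        d = self.decision(X)
        return expit(self.platt_slope * d + self.platt_intercept)


def train_weighted_svm(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    C: float = 1.0,
    gamma: float = 1.0,
    seed: int = 0,
) -> TrainedModel:
    """Class-weighted linear SVM with Platt-style posterior calibration.

    The minority class's misclassification cost is ``gamma`` times the
    inverse-class-frequency baseline (so gamma = 1 corresponds to balanced
    weighting); the majority class has cost 1. The posterior map is a
    sigmoid of the decision value fitted by logistic regression on the
    training data.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary training requires exactly two classes, got {classes.size}")
    ybin = (y == classes[1]).astype(int)
    n0, n1 = np.bincount(ybin, minlength=2)
    minority = 0 if n0 <= n1 else 1
    weights = {0: 1.0, 1: 1.0}
    weights[minority] = gamma * (max(n0, n1) / min(n0, n1))

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svm = SVC(kernel="linear", C=C, class_weight=weights, random_state=seed)
    svm.fit(Xs, ybin)
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    d = Xs @ w + b
    # The sigmoid map carries the same class costs as the SVM so that the
    # posterior-0.5 boundary honours the minority-class weighting.
    sample_weight = np.where(ybin == 1, weights[1], weights[0])
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(d.reshape(-1, 1), ybin, sample_weight=sample_weight)
    return TrainedModel(
        weights=w,
        bias=b,
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        platt_slope=float(lr.coef_[0, 0]),
        platt_intercept=float(lr.intercept_[0]),
        C=C,
        gamma=gamma,
    )


@dataclass(eq=False)
class ROCResult:
    """ROC sweep over posterior thresholds, with the chosen operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    posteriors: np.ndarray
    y: np.ndarray
    operating_threshold: float | None = None
    operating_sensitivity: float | None = None
    operating_specificity: float | None = None
    operating_accuracy: float | None = None
    confusion: np.ndarray | None = None


def roc_curve(posteriors: Sequence[float], y: Sequence[int]) -> ROCResult:
    """ROC curve by sweeping the posterior threshold lambda over [0, 1].

    A measurement is called positive when p >= lambda. The sweep visits
    every distinct posterior plus the endpoints 0 and 1; the AUC is the
    trapezoidal integral over (1 - specificity, sensitivity), which equals
    the pairwise concordance probability with ties counted 1/2.
    """
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(y).astype(int)
    if p.ndim != 1 or p.shape != y.shape:
        raise ValueError("posteriors and labels must be 1-D and aligned")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    thresholds = np.unique(np.concatenate([p, [0.0, 1.0]]))[::-1]
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, lam in enumerate(thresholds):
        pred = p >= lam
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens[i] = tp / n_pos
        spec[i] = 1.0 - fp / n_neg

    fpr = 1.0 - spec
    # Integration path includes the all-negative corner (0, 0) even when the
    # largest posterior equals 1.
    fpr_path = np.concatenate([[0.0], fpr])
    tpr_path = np.concatenate([[0.0], sens])
    order = np.lexsort((tpr_path, fpr_path))
    auc = float(np.trapezoid(tpr_path[order], fpr_path[order]))
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc, posteriors=p, y=y)


def operating_point(roc: ROCResult) -> tuple[float, float, float, float]:
    """Curve point with the smallest Euclidean distance to the top-left corner.

    Ties (to within 1e-12) are broken toward the higher sensitivity — in a
    margin-assessment setting a missed positive margin is the costlier
    error. Returns (lambda*, sensitivity, specificity, accuracy) and fills
    the corresponding fields of *roc*, including the confusion matrix
    [[tn, fp], [fn, tp]] at lambda*.
    """
    d = np.sqrt((1.0 - roc.specificity) ** 2 + (1.0 - roc.sensitivity) ** 2)
    best = d.min()
    tied = np.flatnonzero(d <= best + 1e-12)
    i = tied[np.argmax(roc.sensitivity[tied])]
    lam = float(roc.thresholds[i])
    pred = roc.posteriors >= lam
    tp = int(np.sum(pred & (roc.y == 1)))
    fp = int(np.sum(pred & (roc.y == 0)))
    fn = int(np.sum(~pred & (roc.y == 1)))
    tn = int(np.sum(~pred & (roc.y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / roc.y.size
    roc.operating_threshold = lam
    roc.operating_sensitivity = sens
    roc.operating_specificity = spec
    roc.operating_accuracy = acc
    roc.confusion = np.array([[tn, fp], [fn, tp]])
    return lam, sens, spec, acc


@dataclass(eq=False)
class GridSearchResult:
    best_c: float
    best_gamma: float
    best_mean_auc: float
    pooled_posteriors: np.ndarray
    pooled_y: np.ndarray
    folds: np.ndarray
    report: pd.DataFrame


def grid_search_cv(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    groups: Sequence,
    spec: ModelSpec,
) -> GridSearchResult:
    """Grid search over (C, gamma) with patient-grouped k-fold CV.

    For every grid point each fold's model is trained on the other folds
    and scored by held-out AUC; the grid point with the best mean fold AUC
    wins, and its pooled held-out posteriors are returned for the final ROC.
    Patient disjointness between train and test is asserted for every fold.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    folds = make_grouped_folds(groups, k=spec.n_folds, seed=spec.seed)

    rows = []
    pooled: dict[tuple[float, float], np.ndarray] = {}
    for C in spec.c_grid:
        for gamma in spec.gamma_grid:
            post = np.full(y.size, np.nan)
            for k in range(spec.n_folds):
                test = folds == k
                train = ~test
                if set(groups[train]) & set(groups[test]):
                    raise AssertionError("patient leakage between train and test folds")
                fold_auc = np.nan
                if np.unique(y[train]).size == 2:
                    model = train_weighted_svm(X[train], y[train], C=C, gamma=gamma, seed=spec.seed)
                    p = model.posterior(X[test])
                    post[test] = p
                    if np.unique(y[test]).size == 2:
                        fold_auc = roc_curve(p, y[test]).auc
                rows.append({"C": C, "gamma": gamma, "fold": k,
                             "auc": fold_auc, "n_test": int(test.sum())})
            pooled[(C, gamma)] = post
    report = pd.DataFrame(rows)
    mean_auc = report.groupby(["C", "gamma"])["auc"].mean()
    best_c, best_gamma = mean_auc.idxmax()
    best_post = pooled[(best_c, best_gamma)]
    if np.any(np.isnan(best_post)):
        raise ValueError("pooled posteriors incomplete: a fold's training set was degenerate")
    return GridSearchResult(
        best_c=float(best_c),
        best_gamma=float(best_gamma),
        best_mean_auc=float(mean_auc.max()),
        pooled_posteriors=best_post,
        pooled_y=y,
        folds=folds,
        report=report,
    )


def run_model(
    features: FeatureMatrix,
    model_id: str,
    spec: ModelSpec | None = None,
) -> dict:
    """Full model pipeline: band selection, grouped grid-search CV, ROC, operating point."""
    spec = replace(spec, model_id=model_id) if spec is not None else ModelSpec(model_id=model_id)
    positive, negatives = MODEL_DICHOTOMIES[model_id]
    mask = np.isin(features.labels, [positive, *negatives])
    sub = features.subset(mask)
    if np.unique(sub.labels).size < 2:
        raise ValueError(f"dichotomy {model_id} needs both classes present")
    ybin = (sub.labels == positive).astype(int)

    ranking = l1_rank_features(
        sub.values, ybin, max_features=spec.max_features, seed=spec.seed, groups=sub.patients
    )
    Xr = sub.values[ranking.retained]
    grid = grid_search_cv(Xr, ybin, sub.patients, spec)
    roc = roc_curve(grid.pooled_posteriors, ybin)
    lam, sens, spc, acc = operating_point(roc)

    fold_acc = []
    for k in range(spec.n_folds):
        test = grid.folds == k
        pred = grid.pooled_posteriors[test] >= lam
        fold_acc.append(float(np.mean(pred == (ybin[test] == 1))))
    return {
        "model_id": model_id,
        "positive_class": positive,
        "n_measurements": int(mask.sum()),
        "retained_bands": ranking.retained,
        "band_weights": {n: float(ranking.weights[n]) for n in ranking.retained},
        "best_c": grid.best_c,
        "best_gamma": grid.best_gamma,
        "cv_mean_auc": grid.best_mean_auc,
        "auc": roc.auc,
        "operating_threshold": lam,
        "sensitivity": sens,
        "specificity": spc,
        "accuracy": acc,
        "fold_accuracies": fold_acc,
        "fold_mean_accuracy": float(np.mean(fold_acc)),
        "confusion": roc.confusion.tolist(),
        "roc": roc,
        "grid_report": grid.report,
    }


def accumulation_study(
    acquisitions: Sequence[RawAcquisition],
    manifest: pd.DataFrame,
    standard,
    calibration,
    pre_config=None,
    n_list: Sequence[int] = (10, 5, 1),
    model_ids: Sequence[str] = ("B",),
    qc_threshold: float = 0.6,
    model_spec: ModelSpec | None = None,
) -> dict[int, dict[str, dict]]:
    """Re-run the full pipeline and models with acquisitions truncated to N repeats.

    Emulates shortening the total interrogation time: for each N in
    ``n_list`` every acquisition keeps only its first N accumulations and
    the entire dataset build (preprocessing, QC, labeling, screen) plus
    model training is repeated.
    """
    from .cohort import build_dataset  # local import to avoid a cycle

    results: dict[int, dict[str, dict]] = {}
    for n in n_list:
        truncated = [a.truncated(n) for a in acquisitions]
        bundle = build_dataset(
            truncated, manifest, standard, calibration,
            pre_config=pre_config, qc_threshold=qc_threshold,
        )
        results[n] = {
            m: run_model(bundle.features, m, spec=model_spec) for m in model_ids
        }
    return results
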