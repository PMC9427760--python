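"""Atrophy grading: VRS binarization and regularized logistic regression.

Per brain region (frontal, parietal, left/right medial temporal), the
ordinal visual rating score is binarized (scores >= 2 are positive,
matching clinical convention for both the 0-3 and 0-4 scales) and a
regularized logistic regression is fitted on the eight global-atrophy
features.  Hyperparameters (penalty type, regularization strength,
solver) are tuned by random search under threefold subject-level
cross-validation; performance is summarized by the ROC curve, its AUC,
and the operating point maximizing Youden's index J = SENS + SPEC - 1.
Feature importances are the coefficient magnitudes on the standardized
feature scale, normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import ParameterSampler

from .segmentation import make_folds

__all__ = [
    "REGIONS",
    "REGION_SCALE_MAX",
    "FEATURE_NAMES",
    "RatingRecord",
    "HyperSearchSpec",
    "FittedGrader",
    "GraderResult",
    "binarize_vrs",
    "fit_grader",
    "roc_and_auc",
    "youden_cutoff",
    "evaluate_cv",
    "feature_importance",
]

REGIONS = ("FA", "PA", "MTAR", "MTAL")

#: Maximum visual-rating score per region (FA/PA: 0-3; MTA: 0-4).
REGION_SCALE_MAX = {"FA": 3, "PA": 3, "MTAR": 4, "MTAL": 4}

FEATURE_NAMES = ("GMR3D", "WMR3D", "GMWMR3D", "Ven3D", "GMR2D", "WMR2D", "GMWMR2D", "Ven2D")


@dataclass(frozen=True)
class RatingRecord:
    """One subject's visual rating for one region, with its binary label."""

    subject_id: str
    region: str
    vrs_score: int
    binary_label: bool


def binarize_vrs(score: int, region: str) -> bool:
    """Binarize a visual rating score: positive iff score >= 2.

    FA/PA scores 0-1 are negative, 2-3 positive; MTA scores 0-1 are
    negative, 2-4 positive.  Out-of-scale scores are rejected.
    """
    if region not in REGION_SCALE_MAX:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    smax = REGION_SCALE_MAX[region]
    score = int(score)
    if not 0 <= score <= smax:
        raise ValueError(f"score {score} out of scale 0-{smax} for region {region}")
    return score >= 2


@dataclass(frozen=True)
class HyperSearchSpec:
    """Random-search space for the regularized logistic regression."""

    penalty_options: tuple[str, ...] = ("l1", "l2")
    strength_range: tuple[float, float] = (1e-3, 1e3)
    solver_options: tuple[str, ...] = ("liblinear", "saga")
    n_draws: int = 50
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.strength_range[0] <= 0 or self.strength_range[1] <= 0:
            raise ValueError("strength_range endpoints must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class FittedGrader:
    """A tuned, refitted logistic regression with its standardization."""

    model: LogisticRegression
    mean_: np.ndarray
    std_: np.ndarray
    kept: np.ndarray  # boolean mask over the original feature columns
    chosen_hyperparams: dict
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row of X."""
        X = np.asarray(X, dtype=np.float64)[:, self.kept]
        Z = (X - self.mean_) / self.std_
        return self.model.predict_proba(Z)[:, 1]

    @property
    def coefficients(self) -> np.ndarray:
        """Length-8 coefficient vector on the standardized scale.

        Columns dropped as constant carry coefficient 0.
        """
        full = np.zeros(len(self.kept))
        full[self.kept] = self.model.coef_.ravel()
        return full

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])


@dataclass
class GraderResult:
    """Cross-validated grading summary for one region."""

    region: str
    coefficients: np.ndarray
    intercept: float
    chosen_hyperparams: dict
    roc_points: np.ndarray  # (k, 3): fpr, tpr, threshold
    auc: float
    cutoff: float
    sens: float
    spec: float
    acc: float
    youden_j: float
    importance: np.ndarray

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "chosen_hyperparams": dict(self.chosen_hyperparams),
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sens": self.sens,
            "spec": self.spec,
            "acc": self.acc,
            "youden_j": self.youden_j,
            "importance": {n: float(v) for n, v in zip(FEATURE_NAMES, self.importance)},
        }


def _validate_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2:
        raise ValueError("features must be a 2D table (subjects x features)")
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    if np.isnan(X).any():
        raise ValueError("missing values in features")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 subjects per class, got {n_pos} positive / {n_neg} negative"
        )
    return X, y


def _make_model(params: dict, seed: int) -> LogisticRegression:
    # penalty expressed through l1_ratio: 1.0 = lasso, 0.0 = ridge
    return LogisticRegression(
        l1_ratio=1.0 if params["penalty"] == "l1" else 0.0,
        C=params["C"],
        solver=params["solver"],
        max_iter=5000,
        tol=1e-5,
        random_state=seed,
    )


def _sample_params(spec: HyperSearchSpec) -> list[dict]:
    lo, hi = spec.strength_range
    rng = np.random.default_rng(spec.seed)
    draws = []
    # log-uniform strength; penalty and solver uniform over their options
    sampler = ParameterSampler(
        {
            "penalty": list(spec.penalty_options),
            "solver": list(spec.solver_options),
            "logC": list(np.linspace(0, 1, 101)),
        },
        n_iter=spec.n_draws,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    for p in sampler:
        c = float(np.exp(np.log(lo) + p["logC"] * (np.log(hi) - np.log(lo))))
        draws.append({"penalty": p["penalty"], "solver": p["solver"], "C": c})
    return draws


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def fit_grader(X, y, spec: HyperSearchSpec | None = None) -> FittedGrader:
    """Tune and fit the regularized logistic regression.

    Features are z-scored with training statistics (the eight features mix
    [0,1] ratios with raw voxel counts, so regularization would otherwise
    be unit-dependent and coefficient magnitudes incomparable).  Constant
    features are dropped with a warning.  ``n_draws`` hyperparameter
    settings are sampled and scored by mean AUC over ``cv_folds``
    subject-level folds; the best setting is refit on all data.
    """
    spec = spec or HyperSearchSpec()
    X, y = _validate_xy(X, y)
    col_scale = np.maximum(1.0, np.abs(X).max(axis=0))
    kept = X.std(axis=0) > 1e-12 * col_scale  # tolerate float error on constant columns
    if not kept.all():
        dropped = [i for i, k in enumerate(kept) if not k]
        warnings.warn(f"dropping constant feature columns {dropped}", stacklevel=2)
    if not kept.any():
        raise ValueError("all features are constant")
    Xk = X[:, kept]

    folds = make_folds(np.arange(len(y)), spec.cv_folds, seed=spec.seed)
    draws = _sample_params(spec)
    best_score, best_params = -np.inf, None
    for params in draws:
        aucs = []
        for f in range(spec.cv_folds):
            test = np.array([folds.fold_of_subject[i] == f for i in range(len(y))])
            train = ~test
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                continue
            mean, std = _standardize_fit(Xk[train])
            model = _make_model(params, spec.seed)
            model.fit((Xk[train] - mean) / std, y[train])
            scores = model.predict_proba((Xk[test] - mean) / std)[:, 1]
            aucs.append(roc_auc_score(y[test], scores))
        score = float(np.mean(aucs)) if aucs else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise ValueError("no hyperparameter draw could be scored (degenerate folds)")

    mean, std = _standardize_fit(Xk)
    model = _make_model(best_params, spec.seed)
    model.fit((Xk - mean) / std, y)
    return FittedGrader(
        model=model, mean_=mean, std_=std, kept=kept,
        chosen_hyperparams={**best_params, "cv_auc": best_score},
    )


def roc_and_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve over all distinct score thresholds, and its AUC.

    The AUC equals the probability that a random positive outranks a
    random negative, ties counted one half (the rank-statistic identity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr, thr]), auc


def youden_cutoff(
    roc_points: np.ndarray, n_pos: int, n_neg: int
) -> tuple[float, float, float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity (the screening convention).
    Returns ``(cutoff, sens, spec, acc, youden_j)``; accuracy is computed
    at that cutoff from the class counts.
    """
    pts = np.asarray(roc_points, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("roc_points must be nonempty")
    fpr, tpr, thr = pts[:, 0], pts[:, 1], pts[:, 2]
    j = tpr - fpr
    candidates = np.flatnonzero(j >= j.max() - 1e-12)
    best = candidates[np.argmax(tpr[candidates])]
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    acc = float((sens * n_pos + spec * n_neg) / (n_pos + n_neg))
    return float(thr[best]), sens, spec, acc, float(sens + spec - 1.0)


def feature_importance(coefficients) -> np.ndarray:
    """Normalized coefficient magnitudes: |c_i| / sum_j |c_j|.

    Meaningful only on the standardized feature scale; rejects an
    all-zero coefficient vector.
    """
    c = np.abs(np.asarray(coefficients, dtype=np.float64))
    total = c.sum()
    if total == 0:
        raise ValueError("all coefficients are zero; importance undefined")
    return c / total


def evaluate_cv(X, y, spec: HyperSearchSpec | None = None, region: str = "") -> GraderResult:
    """Cross-validated grading for one region.

    Hyperparameters are tuned once by random search (threefold CV by
    default).  Out-of-fold predicted probabilities are then pooled over
    the folds into a single ROC curve, from which the AUC and the
    Youden-optimal operating point are reported.  Final coefficients and
    importances come from a fit on all data with the chosen setting.
    """
    spec = spec or HyperSearchSpec()
    X, y = _validate_xy(X, y)
    fitted = fit_grader(X, y, spec)
    params = {k: v for k, v in fitted.chosen_hyperparams.items() if k != "cv_auc"}

    # out-of-fold scores with the chosen hyperparameters (fold seed offset
    # from the tuning folds to avoid reusing the selection split)
    folds = make_folds(np.arange(len(y)), spec.cv_folds, seed=spec.seed + 1)
    oof = np.full(len(y), np.nan)
    Xk = X[:, fitted.kept]
    for f in range(spec.cv_folds):
        test = np.array([folds.fold_of_subject[i] == f for i in range(len(y))])
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: training labels single-class; need a larger cohort")
        mean, std = _standardize_fit(Xk[train])
        model = _make_model(params, spec.seed)
        model.fit((Xk[train] - mean) / std, y[train])
        oof[test] = model.predict_proba((Xk[test] - mean) / std)[:, 1]

    roc_points, auc = roc_and_auc(oof, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    cutoff, sens, specificity, acc, j = youden_cutoff(roc_points, n_pos, n_neg)
    coefs = fitted.coefficients
    if np.any(coefs != 0):
        importance = feature_importance(coefs)
    else:
        # regularization shrank every coefficient to zero: no feature is
        # preferred, so report uniform importances rather than failing
        warnings.warn("all coefficients zero after regularization; "
                      "importances set uniform", stacklevel=2)
        importance = np.full(len(coefs), 1.0 / len(coefs))
    return GraderResult(
        region=region,
        coefficients=coefs,
        intercept=fitted.intercept,
        chosen_hyperparams=fitted.chosen_hyperparams,
        roc_points=roc_points,
        auc=auc,
        cutoff=cutoff,
        sens=sens,
        spec=specificity,
        acc=acc,
        youden_j=j,
        importance=importance,
    )
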