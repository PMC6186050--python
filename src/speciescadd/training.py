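"""L2-regularized logistic classifier on the annotation matrix.

The classifier separates simulated (label 1) from derived (label 0)
variants. Features are standardized by dividing by their standard
deviation only — no centering, so exact zeros stay exact zeros and
sparsity is preserved. The penalized objective is mean logistic loss
+ lambda * ||beta||^2 with the intercept unpenalized; the iteration cap
is the optimizer's outer-iteration limit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import SpeciesCaddError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

#: named hyperparameter presets (lambda, max_iter)
PROFILES = {"mouse": (0.1, 100), "human": (1.0, 10)}


@dataclass
class TrainConfig:
    l2_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    iter_grid: tuple[int, ...] = (10, 100)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.l2_grid or not self.iter_grid:
            raise SpeciesCaddError("hyperparameter grids must be non-empty")
        if self.cv_folds < 2:
            raise SpeciesCaddError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    """Per-feature weights plus the frozen scaling factors they expect."""

    feature_names: list[str]
    betas: np.ndarray
    intercept: float
    scale_factors: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    label_convention: str = "simulated=1"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.scale_factors = np.asarray(self.scale_factors, dtype=float)
        if not (len(self.feature_names) == len(self.betas) == len(self.scale_factors)):
            raise SpeciesCaddError("feature_names/betas/scale_factors lengths disagree")
        if np.any(self.scale_factors <= 0):
            raise SpeciesCaddError("scale factors must be positive")

    def to_dict(self) -> dict:
        return {
            "format": "speciescadd-trained-model-v1",
            "feature_names": list(self.feature_names),
            "betas": self.betas.tolist(),
            "intercept": float(self.intercept),
            "scale_factors": self.scale_factors.tolist(),
            "hyperparams": dict(self.hyperparams),
            "label_convention": self.label_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            feature_names=list(d["feature_names"]),
            betas=np.array(d["betas"], dtype=float),
            intercept=float(d["intercept"]),
            scale_factors=np.array(d["scale_factors"], dtype=float),
            hyperparams=dict(d.get("hyperparams", {})),
            label_convention=d.get("label_convention", "simulated=1"),
        )


def fit_scaler(matrix: FeatureMatrix) -> np.ndarray:
    """Per-column population standard deviations (constant columns get 1).

    Scaling divides values by these factors and never subtracts a mean, so
    zero entries remain exactly zero.
    """
    if matrix.n_variants == 0 or not matrix.columns:
        raise SpeciesCaddError("cannot fit a scaler on an empty matrix")
    X = matrix.values_array()
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        names = [matrix.columns[i].name for i in np.flatnonzero(zero)]
        logger.warning("constant column(s) get scale factor 1: %s", names)
        sd = np.where(zero, 1.0, sd)
    return sd


def scale(X: np.ndarray, factors: np.ndarray) -> np.ndarray:
    return X / factors


def fit_logistic(
    X_scaled: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Minimize mean logistic loss + lam * ||beta||^2 (intercept unpenalized).

    Returns (betas, intercept). Deterministic for fixed inputs: lbfgs is a
    batch quasi-Newton method, capped at max_iter outer iterations.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise SpeciesCaddError("training labels contain a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise SpeciesCaddError("labels must be 0 (derived) or 1 (simulated)")
    n = len(y)
    # sklearn objective: 0.5 ||w||^2 + C * sum(loss)  ==  scaled mean-loss
    # objective with lambda = 1 / (2 n C)
    C = 1.0 / (2.0 * n * lam)
    clf = LogisticRegression(
        C=C,
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-10,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_scaled, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def train_model(
    matrix: FeatureMatrix,
    lam: float,
    max_iter: int,
    seed: int = 0,
    exclude_fold: int | None = None,
    scale_factors: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the classifier on the matrix (optionally excluding a held-out fold).

    Scale factors are computed on the FULL matrix (before any fold split)
    and frozen into the model, so downstream sets are standardized
    identically.
    """
    if matrix.labels is None:
        raise SpeciesCaddError("matrix has no class labels")
    if scale_factors is None:
        scale_factors = fit_scaler(matrix)
    X = scale(matrix.values_array(), scale_factors)
    y = matrix.labels
    if exclude_fold is not None:
        keep = matrix.folds() != exclude_fold
        X, y = X[keep], y[keep]
    betas, intercept = fit_logistic(X, y, lam, max_iter, seed)
    return TrainedModel(
        feature_names=matrix.names(),
        betas=betas,
        intercept=intercept,
        scale_factors=scale_factors,
        hyperparams={"lambda": lam, "max_iter": max_iter},
    )


def cross_validate(
    matrix: FeatureMatrix, config: TrainConfig | None = None
) -> tuple[float, int, pd.DataFrame]:
    """Grid-search (lambda, max_iter) by stratified cross-validated ROC-AUC.

    The designated held-out fold (largest fold id) is excluded throughout.
    If the remaining fold ids form exactly cv_folds groups they are used as
    the CV partition (the pre-built training partitions); otherwise a
    seeded stratified split is drawn. Ties break toward larger lambda,
    then smaller max_iter.
    """
    from .evaluation import roc_auc

    config = config or TrainConfig()
    if matrix.labels is None:
        raise SpeciesCaddError("matrix has no class labels")
    folds = matrix.folds()
    if (folds < 0).any():
        raise SpeciesCaddError("cross_validate requires fold ids on every variant")
    held_out = folds.max()
    keep = folds != held_out
    X_full = matrix.values_array()[keep]
    y = matrix.labels[keep]
    sub_folds = folds[keep]
    scale_factors = fit_scaler(matrix)
    X_full = scale(X_full, scale_factors)

    unique_folds = np.unique(sub_folds)
    if len(unique_folds) == config.cv_folds:
        splits = [
            (sub_folds != f, sub_folds == f) for f in unique_folds.tolist()
        ]
    else:
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        splits = [
            (np.isin(np.arange(len(y)), tr), np.isin(np.arange(len(y)), va))
            for tr, va in skf.split(X_full, y)
        ]

    rows = []
    for lam in config.l2_grid:
        for max_iter in config.iter_grid:
            aucs = []
            failed = False
            for train_mask, val_mask in splits:
                try:
                    betas, intercept = fit_logistic(
                        X_full[train_mask], y[train_mask], lam, max_iter, config.seed
                    )
                except SpeciesCaddError:
                    failed = True
                    break
                scores = X_full[val_mask] @ betas + intercept
                aucs.append(roc_auc(scores, y[val_mask]))
            rows.append(
                {
                    "lambda": lam,
                    "max_iter": max_iter,
                    "mean_auc": np.nan if failed else float(np.mean(aucs)),
                }
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_auc"])
    if valid.empty:
        raise SpeciesCaddError("every grid point failed to fit")
    best = valid.sort_values(
        by=["mean_auc", "lambda", "max_iter"], ascending=[False, False, True]
    ).iloc[0]
    return float(best["lambda"]), int(best["max_iter"]), table


def score(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Linear log-odds scores beta . x_scaled + intercept.

    The matrix may carry extra columns (ignored); missing model features
    are an error. Standardization uses the model's frozen scale factors.
    """
    available = {c.name: c for c in matrix.columns}
    absent = [name for name in model.feature_names if name not in available]
    if absent:
        raise SpeciesCaddError(f"matrix lacks model feature(s): {absent}")
    if matrix.has_missing():
        raise SpeciesCaddError("matrix has missing values; run impute_missing first")
    X = np.column_stack([available[name].values for name in model.feature_names])
    return scale(X, model.scale_factors) @ model.betas + model.intercept
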