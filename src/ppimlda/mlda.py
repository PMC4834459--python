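"""Maximum-uncertainty linear discriminant analysis (MLDA) and LOOCV.

Classical Fisher LDA is unusable when the number of voxels p vastly exceeds
the number of subjects n: the pooled within-class covariance Sp is singular.
The maximum-uncertainty (maximum-entropy) remedy replaces every eigenvalue of
Sp that falls below the average eigenvalue with that average,

    Sp = Phi Lambda Phi',   lambda_i* = max(lambda_i, lambda_bar),
    lambda_bar = trace(Sp) / p,     S* = Phi Lambda* Phi',

which expands the least-reliable (smallest-variance) directions toward an
isotropic prior while leaving well-estimated directions untouched.  The
discriminant is then

    w = S*^{-1} (mu_1 - mu_2),   b = -w'(mu_1 + mu_2)/2,
    z(x) = w'x + b,

with patients the positive class (z > 0 predicts patient).  Because at most
n - 2 eigenvalues are nonzero, S*^{-1} is applied through the spectral
shortcut

    S*^{-1} = (1/lambda_bar) (I - Phi_r Phi_r') + Phi_r diag(1/lambda_i*) Phi_r'

where Phi_r spans the nonzero-eigenvalue subspace of the within-class
centered data, so no p x p matrix is ever formed.

There is deliberately no tunable hyperparameter (no cost, no shrinkage
weight); the only analysis choice is the feature-selection fraction, and
feature selection is re-run inside every cross-validation fold to avoid
information leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ppi import FeatureIndex
from .volume import VolumeGrid

#: numerical floor separating "nonzero" singular values, relative to the largest
_RANK_RTOL = 1e-10


@dataclass
class MLDAModel:
    """Fitted discriminant over (optionally selected) features."""

    w: np.ndarray
    b: float
    selected_idx: np.ndarray | None
    eigvals_raw: np.ndarray
    eigvals_reg: np.ndarray
    lambda_bar: float
    class_means: dict[int, np.ndarray]
    n_features_total: int
    lambda_bar_rule: str = "trace_p"

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """z = w'x + b for each row of X (X over the *original* feature space
        when the model carries a feature selection)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_total:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_total}"
            )
        if self.selected_idx is not None:
            X = X[:, self.selected_idx]
        return X @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 (patient) where z > 0, else 0 (control)."""
        return (self.decision_values(X) > 0).astype(int)


def _validate_xy(
    X: np.ndarray, y: np.ndarray, min_per_class: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2D (subjects x features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y must have one label per row of X")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0 (control) or 1 (patient)")
    for cls in (0, 1):
        if (y == cls).sum() < min_per_class:
            raise ValueError(
                f"class {cls} needs at least {min_per_class} sample(s)"
            )
    return X, y


def fit_mlda(
    X: np.ndarray,
    y: np.ndarray,
    lambda_bar_rule: str = "trace_p",
) -> MLDAModel:
    """Fit MLDA on all columns of X (no feature selection).

    Parameters
    ----------
    X, y:
        ``n x p`` feature matrix and binary labels (1 = patient).
    lambda_bar_rule:
        ``"trace_p"`` (default): lambda_bar = trace(Sp)/p, the mean over all p
        eigenvalues including the structural zeros.  ``"nonzero"``: mean over
        the nonzero spectrum only — a stricter shrinkage target offered
        because the ranking criterion is described only loosely in the
        literature this follows.
    """
    # a single sample in one class is tolerated so LOOCV folds of a minimal
    # 2+2 cohort remain fittable; n >= 3 keeps the pooled denominator positive
    X, y = _validate_xy(X, y, min_per_class=1)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples to pool within-class variance")
    mu1 = X[y == 1].mean(axis=0)
    mu0 = X[y == 0].mean(axis=0)

    # within-class centered data; Sp = Xc'Xc / (n-2) (unbiased pooled)
    Xc = X.copy()
    Xc[y == 1] -= mu1
    Xc[y == 0] -= mu0
    denom = n - 2
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    nonzero = s > (s[0] * _RANK_RTOL if s.size and s[0] > 0 else np.inf)
    evals = (s[nonzero] ** 2) / denom  # nonzero eigenvalues of Sp, descending
    phi_r = vt[nonzero].T  # p x r orthonormal basis

    trace = float(evals.sum())
    if trace <= 0:
        raise ValueError("zero total variance: cannot regularize the spectrum")
    if lambda_bar_rule == "trace_p":
        lambda_bar = trace / p
    elif lambda_bar_rule == "nonzero":
        lambda_bar = trace / len(evals)
    else:
        raise ValueError(f"unknown lambda_bar_rule: {lambda_bar_rule!r}")

    evals_reg = np.maximum(evals, lambda_bar)
    d = mu1 - mu0
    proj = phi_r.T @ d
    # S*^{-1} d via the spectral shortcut: isotropic part + corrected subspace
    w = (d - phi_r @ proj) / lambda_bar + phi_r @ (proj / evals_reg)
    b = float(-w @ (mu1 + mu0) / 2.0)
    return MLDAModel(
        w=w,
        b=b,
        selected_idx=None,
        eigvals_raw=evals,
        eigvals_reg=evals_reg,
        lambda_bar=lambda_bar,
        class_means={1: mu1, 0: mu0},
        n_features_total=p,
        lambda_bar_rule=lambda_bar_rule,
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.01,
    ranking: str = "weight",
    lambda_bar_rule: str = "trace_p",
) -> np.ndarray:
    """Indices of the most discriminative ceil(fraction * p) features.

    ``ranking="weight"`` (default) ranks by |w_j| of a full-feature MLDA fit —
    the multivariate criterion whose large-magnitude weights are exactly the
    voxels a discriminative weight map highlights.  ``ranking="t"`` ranks by
    the absolute two-sample t statistic, a univariate alternative.  Ties are
    broken by ascending feature index; the returned indices are in rank order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    X, y = _validate_xy(X, y, min_per_class=1)
    p = X.shape[1]
    if ranking == "weight":
        score = np.abs(fit_mlda(X, y, lambda_bar_rule).w)
    elif ranking == "t":
        x1, x0 = X[y == 1], X[y == 0]
        n1, n0 = len(x1), len(x0)
        sp2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n0 - 1) * x0.var(axis=0, ddof=1)) / (
            n1 + n0 - 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.abs(
                (x1.mean(axis=0) - x0.mean(axis=0))
                / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
            )
        score = np.nan_to_num(score, nan=0.0, posinf=np.inf)
    else:
        raise ValueError(f"unknown ranking: {ranking!r}")
    k = math.ceil(fraction * p)
    # stable rank order: descending score, ascending index on ties
    order = np.lexsort((np.arange(p), -score))
    return order[:k]


def fit_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.01,
    ranking: str = "weight",
    lambda_bar_rule: str = "trace_p",
) -> MLDAModel:
    """Feature selection followed by MLDA on the selected columns."""
    sel = select_features(X, y, fraction, ranking, lambda_bar_rule)
    sub = fit_mlda(np.asarray(X, dtype=float)[:, sel], y, lambda_bar_rule)
    sub.selected_idx = sel
    sub.n_features_total = np.asarray(X).shape[1]
    return sub


@dataclass
class CVResult:
    """Leave-one-subject-out outcome: one held-out decision value per subject."""

    decision_values: np.ndarray
    predictions: np.ndarray
    true_labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    fold_models: list[MLDAModel] | None = None

    def __post_init__(self) -> None:
        self.decision_values = np.asarray(self.decision_values, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=int)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        n = len(self.decision_values)
        if not (len(self.predictions) == len(self.true_labels) == n):
            raise ValueError("decision_values, predictions, true_labels must align")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    @property
    def accuracy(self) -> float:
        return float((self.predictions == self.true_labels).mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "true_label": self.true_labels,
                "decision_value": self.decision_values,
                "prediction": self.predictions,
            }
        )


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.01,
    ranking: str = "weight",
    lambda_bar_rule: str = "trace_p",
    subject_ids: list[str] | None = None,
    keep_fold_models: bool = False,
) -> CVResult:
    """Leave-one-subject-out cross-validation of the selection + MLDA pipeline.

    Each subject is scored by a model fit on the remaining n-1 subjects, with
    feature selection recomputed inside the fold so the held-out subject never
    influences which voxels enter the discriminant.
    """
    X, y = _validate_xy(X, y)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    z = np.empty(n)
    models = [] if keep_fold_models else None
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yi = y[mask]
        if len(np.unique(yi)) < 2:
            raise ValueError(f"fold excluding subject {i} loses a class")
        model = fit_pipeline(X[mask], yi, fraction, ranking, lambda_bar_rule)
        z[i] = model.decision_values(X[i : i + 1])[0]
        if models is not None:
            models.append(model)
        mask[i] = True
    return CVResult(
        decision_values=z,
        predictions=(z > 0).astype(int),
        true_labels=y,
        subject_ids=subject_ids or [],
        fold_models=models,
    )


def export_weight_map(model: MLDAModel, index: FeatureIndex) -> VolumeGrid:
    """Back-project discriminant weights into volume space.

    Selected voxels carry their weight; every other voxel (unselected or
    outside the gray-matter mask) is zero.
    """
    if model.n_features_total != index.n_features:
        raise ValueError(
            f"model spans {model.n_features_total} features but index has {index.n_features}"
        )
    full_w = np.zeros(index.n_features)
    if model.selected_idx is None:
        full_w[:] = model.w
    else:
        full_w[model.selected_idx] = model.w
    return index.to_volume(full_w)
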