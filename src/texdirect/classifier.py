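"""Soft-margin SVM with a degree-2 polynomial kernel, CV protocols, metrics.

The classifier is the standard soft-margin machine: minimise
``0.5 <w, w> + C sum xi_i`` subject to ``y_i (<w, x_i> + b) >= 1 - xi_i``,
solved in the dual.  Nonlinearity enters through the inhomogeneous
polynomial kernel

    K(x, x_i) = (<x_i, x> + 1)^d,          d = 2 by default,

which admits quadratic decision boundaries (it separates XOR-type label
patterns that no linear machine can).  The dual QP is delegated to libsvm
via scikit-learn; the fitted machine is re-expressed here through its
support vectors, dual coefficients y_i alpha_i* and bias b*, and predictions
are evaluated directly from the kernel expansion

    g(x) = sign( sum_i y_i alpha_i* K(x, x_i) + b* ),

with the tie sign(0) -> +1 (abnormal), the conservative call for screening.

Evaluation follows the screening conventions: abnormal is the positive
class (+1), normal the negative (-1); CCR is the overall correct fraction,
sensitivity the true-positive rate, specificity the true-negative rate.
Cross-validation is stratified seeded tenfold or leave-one-out; per-fold
metrics that are undefined (a class absent from a test fold) are recorded
as NaN and excluded from the mean +/- sd aggregation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ValidationError

POSITIVE, NEGATIVE = 1, -1


def polynomial_kernel(x, xi, degree: int = 2) -> float:
    """Inhomogeneous polynomial kernel (<xi, x> + 1)^degree."""
    x = np.asarray(x, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    if x.shape != xi.shape:
        raise ValidationError(f"vector length mismatch: {x.shape} vs {xi.shape}")
    if degree < 1:
        raise ValidationError("kernel degree must be >= 1")
    return float((np.dot(xi, x) + 1.0) ** degree)


@dataclass(frozen=True)
class SVMConfig:
    """Kernel degree d and penalty C of the soft-margin objective."""

    degree: int = 2
    C: float = 1.0
    tol: float = 1e-6  # KKT violation tolerance of the QP solver

    def __post_init__(self):
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")
        if self.C <= 0:
            raise ValidationError("C must be positive")


class SVMModel:
    """A trained machine: support vectors, dual coefficients and bias.

    ``decision_function`` evaluates the kernel expansion explicitly from the
    stored support set, so predictions are reproducible from the model's own
    parameters without the solver.
    """

    def __init__(self, support_vectors: np.ndarray, dual_coefs: np.ndarray,
                 bias: float, config: SVMConfig):
        self.support_vectors = np.asarray(support_vectors, dtype=np.float64)
        self.dual_coefs = np.asarray(dual_coefs, dtype=np.float64).ravel()
        self.bias = float(bias)
        self.config = config

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        gram = (X @ self.support_vectors.T + 1.0) ** self.config.degree
        return gram @ self.dual_coefs + self.bias

    def predict(self, X) -> np.ndarray:
        """Labels in {+1, -1}; a decision value of exactly 0 maps to +1."""
        single = np.asarray(X).ndim == 1
        d = self.decision_function(X)
        labels = np.where(d >= 0, POSITIVE, NEGATIVE)
        return int(labels[0]) if single else labels


def train_svm(X, y, config: SVMConfig | None = None) -> SVMModel:
    """Solve the soft-margin dual on a labeled set; both classes required."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n_samples, n_features) aligned with y")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if set(np.unique(y)) != {POSITIVE, NEGATIVE}:
        raise ValidationError("training data must contain both classes (+1/-1)")
    # gamma=1, coef0=1 makes sklearn's poly kernel exactly (<x, xi> + 1)^d
    svc = SVC(kernel="poly", degree=config.degree, gamma=1.0, coef0=1.0,
              C=config.C, tol=config.tol)
    svc.fit(X, y)
    # sklearn's dual_coef_ already carries y_i * alpha_i*
    return SVMModel(support_vectors=svc.support_vectors_,
                    dual_coefs=svc.dual_coef_, bias=svc.intercept_[0],
                    config=config)


@dataclass(frozen=True)
class Metrics:
    """CCR / sensitivity / specificity for one prediction set (fractions)."""

    ccr: float
    sensitivity: float
    specificity: float

    def as_tuple(self):
        return (self.ccr, self.sensitivity, self.specificity)


def compute_metrics(predicted, truth) -> Metrics:
    """Confusion-table rates; a class absent from ``truth`` yields NaN."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or truth.size == 0:
        raise ValidationError("predicted and truth must be equal-length, non-empty")
    correct = predicted == truth
    pos, neg = truth == POSITIVE, truth == NEGATIVE
    ccr = float(correct.mean())
    sens = float(correct[pos].mean()) if pos.any() else math.nan
    spec = float(correct[neg].mean()) if neg.any() else math.nan
    return Metrics(ccr=ccr, sensitivity=sens, specificity=spec)


def _nan_mean_sd(values: np.ndarray) -> tuple[float, float]:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return math.nan, math.nan
    return float(defined.mean()), float(defined.std(ddof=0))


@dataclass
class PerformanceReport:
    """Per-fold and aggregate CCR/sensitivity/specificity of one CV run.

    ``overall`` pools every held-out prediction, so the identity
    CCR = (Se * n_pos + Sp * n_neg) / n holds exactly on it.  Mean and sd
    aggregate the defined per-fold values (population sd, matching the
    mean +/- sd convention of the experiment tables).
    """

    protocol: str
    seed: int
    config: SVMConfig
    per_fold: list[Metrics]
    fold_assignments: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray

    def __post_init__(self):
        self.overall = compute_metrics(self.predictions, self.truth)

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def _stat(self, name: str) -> tuple[float, float]:
        vals = np.array([getattr(m, name) for m in self.per_fold])
        if np.isnan(vals).any():
            warnings.warn(
                f"{int(np.isnan(vals).sum())} fold(s) had undefined {name}; "
                "excluded from mean/sd", stacklevel=2)
        return _nan_mean_sd(vals)

    def mean_sd(self, name: str) -> tuple[float, float]:
        """Mean and sd over folds of 'ccr', 'sensitivity' or 'specificity'."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self._stat(name)

    def to_frame(self):
        """Per-fold metrics as a DataFrame (one row per fold)."""
        import pandas as pd

        return pd.DataFrame(
            [{"fold": i, "ccr": m.ccr, "sensitivity": m.sensitivity,
              "specificity": m.specificity} for i, m in enumerate(self.per_fold)])

    def summary_dict(self) -> dict:
        out = {"protocol": self.protocol, "seed": self.seed,
               "C": self.config.C, "degree": self.config.degree,
               "n_folds": self.n_folds}
        for name in ("ccr", "sensitivity", "specificity"):
            mean, sd = self.mean_sd(name)
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = sd
            out[f"{name}_overall"] = getattr(self.overall, name)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary_dict(), **kwargs)


def make_folds(y, protocol: str, seed: int) -> list[np.ndarray]:
    """Test-index lists for 'tenfold' (stratified, seeded) or 'loocv'."""
    y = np.asarray(y)
    n = y.size
    if protocol == "loocv":
        if n < 3:
            raise ValidationError("leave-one-out requires at least 3 samples")
        return [test for _, test in LeaveOneOut().split(np.zeros((n, 1)))]
    if protocol == "tenfold":
        counts = {c: int((y == c).sum()) for c in (POSITIVE, NEGATIVE)}
        if min(counts.values(), default=0) < 10:
            raise ValidationError(
                f"tenfold requires >= 10 samples per class, got {counts}")
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        return [test for _, test in skf.split(np.zeros((n, 1)), y)]
    raise ValidationError(f"unknown protocol {protocol!r}")


def cross_validate(X, y, config: SVMConfig | None = None,
                   protocol: str = "tenfold", seed: int = 0) -> PerformanceReport:
    """Train/test over the protocol's folds; every sample is tested once."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    folds = make_folds(y, protocol, seed)
    predictions = np.zeros_like(y)
    assignments = np.full(y.size, -1, dtype=int)
    per_fold = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        model = train_svm(X[train_mask], y[train_mask], config)
        pred = model.predict(X[test_idx])
        predictions[test_idx] = pred
        assignments[test_idx] = i
        per_fold.append(compute_metrics(pred, y[test_idx]))
    return PerformanceReport(protocol=protocol, seed=seed, config=config,
                             per_fold=per_fold, fold_assignments=assignments,
                             predictions=predictions, truth=y.copy())
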