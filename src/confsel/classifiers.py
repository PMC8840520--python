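"""From-scratch base learners: logistic regression, Gaussian NB, KNN.

All three are written against plain numpy; scikit-learn is used only in the
test suite as an independent oracle.  Logistic regression minimizes the mean
cross-entropy with an L2 penalty ``(1/(2C)) * ||w||^2`` on the non-intercept
weights via deterministic gradient descent with backtracking line search.
The naive Bayes learner is the Gaussian/MAP variant (the literature sometimes
abbreviates it "GB", not to be confused with gradient boosting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from confsel.datasets import LabeledDataset
from confsel.exceptions import DimensionMismatchError, SingleClassError

_SERIAL_VERSION = 1


def _read_maybe_path(source: str | Path) -> str:
    """Accept either a JSON string or a path to a JSON file."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()


# ---------------------------------------------------------------------------
# standardization helper (shared by LR and KNN)
# ---------------------------------------------------------------------------

def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and scale; zero-variance features get scale 1."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LRModel:
    """Fitted logistic-regression parameters.

    ``intercept`` and ``weights`` act on (optionally standardized) features;
    ``mean``/``scale`` hold the training-set standardization constants when
    ``standardize`` is True.
    """

    intercept: float
    weights: np.ndarray
    C: float
    threshold: float = 0.5
    standardize: bool = True
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    converged: bool = False
    n_iter: int = 0
    final_cost: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format_version": _SERIAL_VERSION,
            "model": "logistic_regression",
            "intercept": float(self.intercept),
            "weights": np.asarray(self.weights, float).tolist(),
            "C": self.C,
            "threshold": self.threshold,
            "standardize": self.standardize,
            "mean": None if self.mean is None else self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_cost": self.final_cost,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LRModel":
        d = json.loads(_read_maybe_path(source))
        return cls(
            intercept=d["intercept"],
            weights=np.asarray(d["weights"], float),
            C=d["C"],
            threshold=d["threshold"],
            standardize=d["standardize"],
            mean=None if d["mean"] is None else np.asarray(d["mean"], float),
            scale=None if d["scale"] is None else np.asarray(d["scale"], float),
            converged=d["converged"],
            n_iter=d["n_iter"],
            final_cost=d["final_cost"],
        )


def logistic_cost_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, C: float
) -> tuple[float, np.ndarray]:
    """Penalized cross-entropy cost and its analytic gradient.

    ``theta[0]`` is the intercept (unpenalized); ``theta[1:]`` the weights.
    Cost = mean_i [ log(1+e^{z_i}) - y_i z_i ] + (1/(2C)) ||theta[1:]||^2,
    evaluated with a numerically stable softplus.
    """
    n = X.shape[0]
    z = theta[0] + X @ theta[1:]
    # log(1 + e^z) - y*z, stable for large |z|
    ce = np.logaddexp(0.0, z) - y * z
    cost = float(ce.mean() + (0.5 / C) * np.dot(theta[1:], theta[1:]))
    p = _sigmoid(z)
    resid = (p - y) / n
    grad = np.empty_like(theta)
    grad[0] = resid.sum()
    grad[1:] = X.T @ resid + theta[1:] / C
    return cost, grad


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_logistic(
    train: LabeledDataset,
    C: float = 5.0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
    threshold: float = 0.5,
    standardize: bool = True,
) -> LRModel:
    """Fit logistic regression by batch gradient descent with backtracking.

    Initialization is the zero vector, so the result does not depend on
    ``seed`` (accepted for interface symmetry).  Converged when the cost
    decrease falls below ``tol``; otherwise stops at ``max_iter``.

    Raises
    ------
    SingleClassError : if only one label value is present.
    """
    counts = train.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise SingleClassError(f"need both classes to fit LR, got {counts}")
    X = train.features
    mean = scale = None
    if standardize:
        mean, scale = _fit_standardizer(X)
        X = (X - mean) / scale
    y = train.labels.astype(float)
    theta = np.zeros(X.shape[1] + 1)
    cost, grad = logistic_cost_grad(theta, X, y, C)
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # backtracking (Armijo) line search from the last accepted step
        step = min(step * 2.0, 1e6)
        gnorm2 = float(grad @ grad)
        while True:
            trial = theta - step * grad
            trial_cost, trial_grad = logistic_cost_grad(trial, X, y, C)
            if trial_cost <= cost - 0.5 * step * gnorm2 or step < 1e-16:
                break
            step *= 0.5
        if not np.isfinite(trial_cost):
            raise FloatingPointError("non-finite LR cost during optimization")
        delta = cost - trial_cost
        theta, cost, grad = trial, trial_cost, trial_grad
        if 0 <= delta < tol:
            converged = True
            break
    return LRModel(
        intercept=float(theta[0]),
        weights=theta[1:],
        C=C,
        threshold=threshold,
        standardize=standardize,
        mean=mean,
        scale=scale,
        converged=converged,
        n_iter=it,
        final_cost=cost,
    )


def predict_logistic(
    model: LRModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities ``sigmoid(b0 + X @ w)`` and labels (1 iff p >= threshold)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.weights.shape[0]:
        raise DimensionMismatchError(
            f"query has {X.shape[1]} features, model expects "
            f"{model.weights.shape[0]}"
        )
    if model.standardize and model.mean is not None:
        X = (X - model.mean) / model.scale
    proba = _sigmoid(model.intercept + X @ model.weights)
    labels = (proba >= model.threshold).astype(int)
    return proba, labels


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class GNBModel:
    """Per-class priors and per-class per-feature Gaussian moments."""

    priors: np.ndarray          # shape (2,), sums to 1
    means: np.ndarray           # shape (2, d)
    variances: np.ndarray       # shape (2, d), floored at var_floor
    var_floor: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format_version": _SERIAL_VERSION,
            "model": "gaussian_nb",
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "var_floor": self.var_floor,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GNBModel":
        d = json.loads(_read_maybe_path(source))
        return cls(
            priors=np.asarray(d["priors"], float),
            means=np.asarray(d["means"], float),
            variances=np.asarray(d["variances"], float),
            var_floor=d["var_floor"],
        )


def fit_gaussian_nb(
    train: LabeledDataset, var_floor: float | None = None
) -> GNBModel:
    """Estimate class priors and per-class Gaussian moments.

    Variances are population variances (divisor n_class) clamped from below
    at ``var_floor``; the default floor is 1e-9 times the largest per-feature
    variance across classes (at least 1e-12 in absolute terms) so constant
    features cannot produce zero variances.
    """
    counts = train.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise SingleClassError(f"need both classes to fit GNB, got {counts}")
    n, d = train.features.shape
    priors = np.array([counts[0] / n, counts[1] / n])
    means = np.zeros((2, d))
    variances = np.zeros((2, d))
    for cls in (0, 1):
        Xc = train.features[train.labels == cls]
        means[cls] = Xc.mean(axis=0)
        variances[cls] = Xc.var(axis=0)  # population variance
    if var_floor is None:
        var_floor = max(1e-9 * float(variances.max(initial=0.0)), 1e-12)
    variances = np.maximum(variances, var_floor)
    return GNBModel(priors=priors, means=means, variances=variances,
                    var_floor=var_floor)


def predict_gaussian_nb(
    model: GNBModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MAP prediction under the naive Gaussian likelihood.

    Returns normalized posteriors of shape (n, 2) and labels; posterior ties
    break toward class 0.
    """
    X = np.atleast_2d(np.asarray(X, float))
    d = model.means.shape[1]
    if X.shape[1] != d:
        raise DimensionMismatchError(
            f"query has {X.shape[1]} features, model expects {d}"
        )
    log_post = np.zeros((X.shape[0], 2))
    for cls in (0, 1):
        mu = model.means[cls]
        var = model.variances[cls]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var)
        log_post[:, cls] = ll.sum(axis=1) + np.log(model.priors[cls])
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    posteriors = np.exp(log_post)
    labels = (log_post[:, 1] > log_post[:, 0]).astype(int)
    return posteriors, labels


# ---------------------------------------------------------------------------
# K-nearest neighbors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KNNConfig:
    """KNN hyperparameters: neighbor count and feature standardization."""

    k: int = 5
    standardize: bool = True


def predict_knn(
    train: LabeledDataset,
    X: np.ndarray,
    config: KNNConfig = KNNConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the K nearest training points (Euclidean).

    Distance ties break toward the lower training-row index (stable sort);
    vote ties (possible for even K) break toward the single nearest
    neighbor's label.  Returns (vote fractions for class 1, labels).
    """
    if config.k < 1 or config.k > train.n_samples:
        raise ValueError(
            f"K={config.k} out of range for {train.n_samples} training rows"
        )
    Xq = np.atleast_2d(np.asarray(X, float))
    if Xq.shape[1] != train.n_features:
        raise DimensionMismatchError(
            f"query has {Xq.shape[1]} features, train has {train.n_features}"
        )
    Xt = train.features
    if config.standardize:
        mean, scale = _fit_standardizer(Xt)
        Xt = (Xt - mean) / scale
        Xq = (Xq - mean) / scale
    y = train.labels
    k = config.k
    labels = np.empty(Xq.shape[0], dtype=int)
    scores = np.empty(Xq.shape[0], dtype=float)
    # squared distances suffice for ranking; chunk queries to bound memory
    chunk = max(1, int(2e7) // max(Xt.shape[0], 1))
    for start in range(0, Xq.shape[0], chunk):
        q = Xq[start:start + chunk]
        d2 = (
            np.sum(q * q, axis=1)[:, None]
            - 2.0 * q @ Xt.T
            + np.sum(Xt * Xt, axis=1)[None, :]
        )
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        votes = y[order]
        ones = votes.sum(axis=1)
        frac = ones / k
        pred = np.where(ones * 2 > k, 1, 0)
        tie = ones * 2 == k
        if np.any(tie):
            pred[tie] = y[order[tie, 0]]
        labels[start:start + len(q)] = pred
        scores[start:start + len(q)] = frac
    return scores, labels
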