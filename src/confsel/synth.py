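"""Synthetic imbalanced descriptor tables.

Two multivariate Gaussian classes sharing an equicorrelated covariance with
log-spaced per-feature scales (emulating the heterogeneous physical scales
of real protein descriptors), class means separated by a prescribed
Mahalanobis distance, and exact class counts.  Class 1 is the minority
("active binding").
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from confsel.datasets import LabeledDataset
from confsel.exceptions import ConfigurationError


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic two-class Gaussian generator.

    ``imbalance_ratio`` r sets minority count = round(n/(r+1)) unless
    ``minority_count`` overrides it to hit exact published-style counts.
    ``separation`` is the Mahalanobis distance between class means.
    ``feature_scale_spread`` is the ratio of the largest to smallest
    per-feature standard deviation (log-spaced).  ``marginals`` may be
    "gaussian" or "lognormal" (model-mismatch option: features are
    exponentiated after generation).
    """

    n_samples: int
    n_features: int = 50
    imbalance_ratio: float = 3.0
    separation: float = 1.5
    feature_scale_spread: float = 10.0
    correlation: float = 0.2
    seed: int = 0
    minority_count: int | None = None
    marginals: str = "gaussian"

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.imbalance_ratio < 1:
            raise ConfigurationError("imbalance_ratio must be >= 1")
        if self.separation < 0:
            raise ConfigurationError("separation must be >= 0")
        if self.feature_scale_spread < 1:
            raise ConfigurationError("feature_scale_spread must be >= 1")
        if not 0 <= self.correlation < 1:
            raise ConfigurationError("correlation must lie in [0, 1)")
        if self.marginals not in ("gaussian", "lognormal"):
            raise ConfigurationError(f"unknown marginals {self.marginals!r}")
        if self.resolved_minority_count() < 2:
            raise ConfigurationError("minority class would have < 2 samples")
        if self.resolved_minority_count() > self.n_samples - 2:
            raise ConfigurationError("majority class would have < 2 samples")

    def resolved_minority_count(self) -> int:
        if self.minority_count is not None:
            return self.minority_count
        return round(self.n_samples / (self.imbalance_ratio + 1))


def _covariance_cholesky(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Scales (per-feature std) and Cholesky factor of the shared covariance."""
    d = spec.n_features
    scales = np.logspace(0.0, np.log10(spec.feature_scale_spread), d)
    rho = spec.correlation
    corr = np.full((d, d), rho)
    np.fill_diagonal(corr, 1.0)
    cov = np.outer(scales, scales) * corr
    return scales, np.linalg.cholesky(cov)


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a labeled dataset with exact class counts per the spec.

    The mean difference is a random direction in whitened space scaled so
    its Mahalanobis norm equals ``spec.separation`` exactly; class 0 sits at
    the origin.  Row order is shuffled so classes interleave.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    d = spec.n_features
    n1 = spec.resolved_minority_count()
    n0 = n - n1

    _, L = _covariance_cholesky(spec)
    u = rng.standard_normal(d)
    u /= np.linalg.norm(u)
    delta = L @ (spec.separation * u)  # Mahalanobis norm == separation

    z = rng.standard_normal((n, d))
    X = z @ L.T
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    X[labels == 1] += delta
    if spec.marginals == "lognormal":
        # model-mismatch option: exponentiate whitened coordinates so each
        # marginal is log-normal while class separation is preserved
        X = np.exp(z + (labels == 1)[:, None] * (spec.separation * u))

    perm = rng.permutation(n)
    X = X[perm]
    labels = labels[perm]
    names = [f"pro_f{j + 1:02d}" for j in range(d)]
    return LabeledDataset(
        features=X,
        labels=labels,
        feature_names=names,
        sample_ids=list(range(n)),
    )


def write_manifest(spec: GeneratorSpec, path: str | Path) -> Path:
    """Write a JSON manifest recording the generator spec and seed."""
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(spec), indent=2))
    return path


ADORA2A_LIKE = GeneratorSpec(
    n_samples=2997, n_features=50, imbalance_ratio=3.0,
    minority_count=850, separation=1.5, seed=0,
)
"""Preset matching the published 3:1 dataset shape (2147 vs 850)."""

OPRK1_LIKE = GeneratorSpec(
    n_samples=2999, n_features=50, imbalance_ratio=20.0,
    minority_count=137, separation=1.5, seed=0,
)
"""Preset matching the published 20:1 dataset shape (2862 vs 137)."""
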