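"""SMOTE oversampling, random undersampling, class-inversion rebalancing.

``invert_class_balance`` builds the second-stage training set: the majority
class (0) is undersampled down to the original minority count, and the
minority class (1) is SMOTE-oversampled up to the original majority count,
so the total training size is preserved exactly while the imbalance flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from confsel.datasets import LabeledDataset
from confsel.exceptions import ResamplingError, SingleClassError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SMOTEConfig:
    """SMOTE hyperparameters.

    ``k`` nearest minority neighbors are candidates for interpolation; the
    interpolation weight is Uniform[0,1] unless ``weight`` pins it to a
    constant (a test hook: weight 0 duplicates original points).
    """

    k: int = 5
    seed: int = 0
    weight: float | None = None


@dataclass(frozen=True)
class RebalancePlan:
    """Target counts for class inversion: keep/synthesize sizes."""

    n_majority_keep: int
    n_minority_target: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_majority_keep < 0 or self.n_minority_target < 0:
            raise ResamplingError("negative rebalance counts")


def smote_oversample(
    minority: np.ndarray, n_new: int, config: SMOTEConfig = SMOTEConfig()
) -> np.ndarray:
    """Generate ``n_new`` synthetic minority points by neighbor interpolation.

    Each synthetic point is ``base + w * (neighbor - base)`` where the base
    cycles round-robin over the minority rows (random bases fill any
    remainder), the neighbor is drawn uniformly from the base's ``k`` nearest
    minority neighbors (Euclidean, self excluded), and ``w ~ Uniform[0,1]``.
    Neighbor search is restricted to the minority class.  ``k`` is clamped to
    ``n_minority - 1`` with a warning when too large.
    """
    minority = np.atleast_2d(np.asarray(minority, float))
    n_min, d = minority.shape
    if n_new < 0:
        raise ResamplingError(f"n_new must be >= 0, got {n_new}")
    if n_new == 0:
        return np.empty((0, d))
    if n_min < 2:
        raise ResamplingError(
            f"SMOTE needs at least 2 minority points, got {n_min}"
        )
    k = config.k
    if k >= n_min:
        logger.warning(
            "SMOTE k=%d >= n_minority=%d; clamping to %d", k, n_min, n_min - 1
        )
        k = n_min - 1
    if k < 1:
        raise ResamplingError("SMOTE neighbor count must be >= 1")
    rng = np.random.default_rng(config.seed)
    # pairwise squared distances among minority points; self excluded via inf
    d2 = (
        np.sum(minority**2, axis=1)[:, None]
        - 2.0 * minority @ minority.T
        + np.sum(minority**2, axis=1)[None, :]
    )
    np.fill_diagonal(d2, np.inf)
    neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]

    n_cycles, remainder = divmod(n_new, n_min)
    bases = np.concatenate([
        np.tile(np.arange(n_min), n_cycles),
        rng.choice(n_min, size=remainder, replace=False)
        if remainder else np.empty(0, dtype=int),
    ]).astype(int)
    picked = neighbor_idx[bases, rng.integers(0, k, size=n_new)]
    if config.weight is not None:
        w = np.full(n_new, float(config.weight))
    else:
        w = rng.uniform(0.0, 1.0, size=n_new)
    base_pts = minority[bases]
    return base_pts + w[:, None] * (minority[picked] - base_pts)


def random_undersample(
    samples: np.ndarray, n_keep: int, seed: int
) -> np.ndarray:
    """Keep ``n_keep`` rows chosen uniformly without replacement.

    Kept rows preserve their original relative order.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    n = samples.shape[0]
    if not 0 <= n_keep <= n:
        raise ResamplingError(f"n_keep={n_keep} out of range for n={n}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    return samples[keep]


def invert_class_balance(
    train: LabeledDataset,
    smote_config: SMOTEConfig = SMOTEConfig(),
    seed: int = 0,
) -> LabeledDataset:
    """Flip the class balance of a training set, preserving its total size.

    The output has class-0 count equal to the original class-1 count
    (random undersampling) and class-1 count equal to the original class-0
    count (all original class-1 rows retained, SMOTE synthetics appended).
    If class 0 is not the majority the set is returned unchanged with a
    warning (no-swap fallback).
    """
    counts = train.class_counts()
    n0, n1 = counts[0], counts[1]
    if n0 == 0 or n1 == 0:
        raise SingleClassError(f"need both classes, got {counts}")
    if n0 < n1:
        logger.warning(
            "class 0 (n=%d) is not the majority (class 1 n=%d); "
            "skipping inversion", n0, n1,
        )
        return train.subset(np.arange(train.n_samples))

    idx0 = np.flatnonzero(train.labels == 0)
    idx1 = np.flatnonzero(train.labels == 1)
    rng = np.random.default_rng(seed)
    keep0 = np.sort(rng.choice(idx0, size=n1, replace=False))

    n_new = n0 - n1
    smote_seeded = SMOTEConfig(
        k=smote_config.k,
        seed=int(rng.integers(0, 2**31 - 1)),
        weight=smote_config.weight,
    )
    synthetic = (
        smote_oversample(train.features[idx1], n_new, smote_seeded)
        if n_new > 0
        else np.empty((0, train.n_features))
    )

    features = np.vstack([
        train.features[keep0],
        train.features[idx1],
        synthetic,
    ])
    labels = np.concatenate([
        np.zeros(n1, dtype=int),
        np.ones(n1, dtype=int),
        np.ones(n_new, dtype=int),
    ])
    ids = (
        [train.sample_ids[i] for i in keep0]
        + [train.sample_ids[i] for i in idx1]
        + [f"smote_{j}" for j in range(n_new)]
    )
    out = LabeledDataset(
        features=features,
        labels=labels,
        feature_names=list(train.feature_names),
        sample_ids=ids,
    )
    assert out.n_samples == train.n_samples
    return out


def provenance_labels(inverted: LabeledDataset) -> list[str]:
    """Per-row "original"/"smote" tags for a set built by inversion."""
    return [
        "smote" if str(s).startswith("smote_") else "original"
        for s in inverted.sample_ids
    ]
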