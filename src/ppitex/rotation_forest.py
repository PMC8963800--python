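"""From-scratch rotation-forest ensemble classifier.

Each ensemble member rotates the feature space before training a decision
tree: the features are randomly partitioned into K disjoint subsets, PCA is
fitted per subset on a bootstrap subsample of the objects (75% of N by
default, drawn with replacement), and the per-subset axes are assembled into
a sparse block-diagonal rotation matrix whose columns are rearranged back to
the original feature order. Class confidences of the L trees are combined by
plain averaging; prediction is the argmax class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.linalg import block_diag
from sklearn.tree import DecisionTreeClassifier

_SCHEMA_VERSION = 1


@dataclass
class RofConfig:
    """Ensemble hyper-parameters. Defaults: L=3 trees, K=10 feature subsets."""

    L: int = 3
    K: int = 10
    bootstrap_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be a positive integer")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass
class FeaturePartition:
    """K disjoint feature-index subsets covering all n features."""

    subsets: list[np.ndarray]
    n_features: int

    def __post_init__(self) -> None:
        concat = np.concatenate(self.subsets) if self.subsets else np.array([], int)
        if len(np.unique(concat)) != self.n_features or len(concat) != self.n_features:
            raise ValueError("subsets must be disjoint and cover all features")


@dataclass
class RotationMatrix:
    """Block-diagonal PCA rotation and its rearrangement to original order."""

    block_diagonal: np.ndarray  # n x n, in permuted (subset-concatenated) order
    rearranged: np.ndarray      # n x n, rows/cols back in original feature order
    partition: FeaturePartition


@dataclass
class _Member:
    rotation: RotationMatrix
    center: np.ndarray  # per-feature bootstrap means, original order
    tree: DecisionTreeClassifier


@dataclass
class RotationForestModel:
    members: list[_Member]
    classes: np.ndarray
    config: RofConfig
    n_features: int
    schema_version: int = field(default=_SCHEMA_VERSION)


def partition_features(n: int, K: int, seed: int | np.random.Generator) -> FeaturePartition:
    """Seeded random partition of {0..n-1} into K nearly equal subsets.

    When K does not divide n, the first (n mod K) subsets get the extra
    feature, so sizes differ by at most one.
    """
    if K > n:
        raise ValueError(f"K={K} exceeds the number of features n={n}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    perm = rng.permutation(n)
    return FeaturePartition(subsets=np.array_split(perm, K), n_features=n)


def bootstrap_indices(
    n_samples: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a bootstrap subsample: round(fraction*N) draws with replacement."""
    size = int(round(fraction * n_samples))
    return rng.integers(0, n_samples, size=size)


def fit_block_rotation(
    X_subset: np.ndarray,
    y: Sequence | None,
    bootstrap_fraction: float,
    seed: int | np.random.Generator,
    return_center: bool = False,
):
    """PCA coefficient block for one feature subset.

    A bootstrap subsample of the objects is drawn, PCA is run on it, and all
    M_j axes are returned as the columns of an M_j x M_j block. Rank-deficient
    subsamples are handled by the SVD's orthonormal completion of the basis,
    so the block is always orthonormal (and hence invertible).
    """
    X_subset = np.asarray(X_subset, dtype=float)
    if X_subset.ndim != 2 or X_subset.shape[0] < 2:
        raise ValueError("need at least 2 samples and a 2-D subset matrix")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    sample = None
    for _ in range(10):  # bounded retries for degenerate draws
        idx = bootstrap_indices(X_subset.shape[0], bootstrap_fraction, rng)
        candidate = X_subset[idx]
        if len(np.unique(candidate, axis=0)) >= 2:
            sample = candidate
            break
    if sample is None:
        raise ValueError("bootstrap subsample degenerate after bounded retries")
    center = sample.mean(axis=0)
    # full_matrices completes missing axes to an orthonormal basis
    _, _, vt = np.linalg.svd(sample - center, full_matrices=True)
    block = vt.T
    if return_center:
        return block, center
    return block


def build_rotation_matrix(
    blocks: Sequence[np.ndarray], partition: FeaturePartition
) -> RotationMatrix:
    """Assemble per-subset blocks into the sparse n x n rotation matrix.

    ``block_diagonal`` acts on features in subset-concatenated order;
    ``rearranged`` is the same map with rows and columns permuted back so it
    can be applied to the original feature layout directly (x @ rearranged).
    """
    if len(blocks) != len(partition.subsets):
        raise ValueError("number of blocks does not match partition")
    for b, s in zip(blocks, partition.subsets):
        if b.shape != (len(s), len(s)):
            raise ValueError(
                f"block shape {b.shape} does not match subset size {len(s)}"
            )
    bd = block_diag(*blocks)
    perm = np.concatenate(partition.subsets)
    rearranged = np.zeros_like(bd)
    rearranged[np.ix_(perm, perm)] = bd
    return RotationMatrix(block_diagonal=bd, rearranged=rearranged, partition=partition)


def _member_rng(seed: int, member: int) -> np.random.Generator:
    # derived per-member streams: reproducible, mutually independent
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(member,)))


def fit(X: np.ndarray, y: Sequence, config: RofConfig | None = None) -> RotationForestModel:
    """Train the rotation forest: L independently rotated unpruned CART trees."""
    config = config or RofConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    n = X.shape[1]
    if config.K > n:
        raise ValueError(f"K={config.K} exceeds feature count n={n}")

    members: list[_Member] = []
    for i in range(config.L):
        rng = _member_rng(config.seed, i)
        partition = partition_features(n, config.K, rng)
        blocks, centers = [], np.empty(n)
        for subset in partition.subsets:
            block, center = fit_block_rotation(
                X[:, subset], y, config.bootstrap_fraction, rng, return_center=True
            )
            blocks.append(block)
            centers[subset] = center
        rotation = build_rotation_matrix(blocks, partition)
        tree = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(2**31))
        )
        tree.fit((X - centers) @ rotation.rearranged, y)
        members.append(_Member(rotation=rotation, center=centers, tree=tree))
    return RotationForestModel(
        members=members, classes=classes, config=config, n_features=n
    )


def predict_proba(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Average of the L trees' class distributions on rotated inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    proba = np.zeros((X.shape[0], len(model.classes)))
    for member in model.members:
        rotated = (X - member.center) @ member.rotation.rearranged
        p = member.tree.predict_proba(rotated)
        # align tree classes (all trees see the full label set, but be safe)
        cols = np.searchsorted(model.classes, member.tree.classes_)
        proba[:, cols] += p
    return proba / len(model.members)


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Argmax class per sample; ties resolve to the earlier class."""
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]


def save_model(model: RotationForestModel, path: str | Path) -> None:
    joblib.dump({"schema_version": _SCHEMA_VERSION, "model": model}, path)


def load_model(path: str | Path) -> RotationForestModel:
    payload = joblib.load(path)
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {payload.get('schema_version')}"
        )
    return payload["model"]


class RotationForest:
    """scikit-learn-style wrapper around the functional fit/predict API."""

    def __init__(self, config: RofConfig | None = None, **kwargs):
        self.config = config or RofConfig(**kwargs)
        self.model_: RotationForestModel | None = None

    def fit(self, X, y) -> "RotationForest":
        self.model_ = fit(X, y, self.config)
        return self

    def _require_fitted(self) -> RotationForestModel:
        if self.model_ is None:
            raise RuntimeError("RotationForest is not fitted")
        return self.model_

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self._require_fitted(), X)

    def predict(self, X) -> np.ndarray:
        return predict(self._require_fitted(), X)

    @property
    def classes_(self) -> np.ndarray:
        return self._require_fitted().classes

    def save(self, path: str | Path) -> None:
        save_model(self._require_fitted(), path)

    @classmethod
    def load(cls, path: str | Path) -> "RotationForest":
        obj = cls()
        obj.model_ = load_model(path)
        obj.config = obj.model_.config
        return obj
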