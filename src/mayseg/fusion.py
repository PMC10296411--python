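"""Concatenation fusion of deep + HOG features and entropy-based selection.

The fused vector is the deep embedding followed by the HOG descriptor
(length ``P = m + D``).  Each of the ``P`` features is then scored by the
Shannon entropy of its empirical distribution and the top ``select_n``
(default 1126) highest-entropy features are kept, original order preserved.

Two probability models for the per-feature distribution:

* ``histogram-over-batch`` (default): a 16-bin histogram of the feature's
  values across the batch, spanning its observed range; a constant feature
  has zero entropy.
* ``softmax-over-sample``: within each sample, a softmax across features
  turns the vector into a distribution; a feature's score averages
  ``-p log p`` of its softmax weight over the batch.

Scores are multiplied by a configurable normalization constant (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSource, FeatureVector

__all__ = ["ProbabilityModel", "FusionConfig", "FusedVector", "concat_features", "entropy_scores", "select_features"]

ProbabilityModel = ("softmax-over-sample", "histogram-over-batch")


@dataclass(frozen=True)
class FusionConfig:
    select_n: int = 1126
    normalization_constant: float = 1.0  # scalar weight on every entropy score
    probability_model: str = "histogram-over-batch"
    n_histogram_bins: int = 16

    def __post_init__(self) -> None:
        if self.select_n < 1:
            raise ValueError("select_n must be >= 1")
        if self.probability_model not in ProbabilityModel:
            raise ValueError(f"unknown probability model {self.probability_model!r}")


@dataclass(frozen=True)
class FusedVector:
    values: np.ndarray
    selected_indices: np.ndarray | None = None  # indices into the full fused vector
    entropy_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.selected_indices is not None:
            idx = np.asarray(self.selected_indices)
            if len(idx) != len(self.values):
                raise ValueError("selected_indices must align with values")
            if np.any(np.diff(idx) <= 0):
                raise ValueError("selected_indices must be strictly increasing")
            object.__setattr__(self, "selected_indices", idx)

    @property
    def dim(self) -> int:
        return len(self.values)


def concat_features(f_res: FeatureVector, f_hog: FeatureVector) -> FusedVector:
    """Deep embedding first, HOG second; ``P = m + D``."""
    if f_res.dim == 0 or f_hog.dim == 0:
        raise ValueError("cannot fuse an empty feature vector")
    return FusedVector(values=np.concatenate([f_res.values, f_hog.values]))


def entropy_scores(batch: np.ndarray, config: FusionConfig | None = None) -> np.ndarray:
    """Per-feature entropy score over a batch of fused vectors (rows)."""
    if config is None:
        config = FusionConfig()
    X = np.asarray(batch, dtype=float)
    if X.ndim != 2:
        raise ValueError("batch must be 2-D (samples x features)")
    n, p = X.shape
    if config.probability_model == "histogram-over-batch":
        if n < 2:
            raise ValueError("histogram-over-batch model needs >= 2 samples")
        scores = np.empty(p)
        for j in range(p):
            col = X[:, j]
            lo, hi = col.min(), col.max()
            if hi <= lo:  # constant feature: degenerate, zero entropy
                scores[j] = 0.0
                continue
            counts, _ = np.histogram(col, bins=config.n_histogram_bins, range=(lo, hi))
            q = counts[counts > 0] / n
            scores[j] = -(q * np.log(q)).sum()
    else:  # softmax-over-sample
        Z = X - X.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        scores = -(P * np.log(np.maximum(P, 1e-300))).mean(axis=0)
    return config.normalization_constant * scores


def select_features(
    fused: FusedVector, scores: np.ndarray, config: FusionConfig | None = None
) -> FusedVector:
    """Keep the ``select_n`` highest-scoring features, original order kept;
    ties broken toward the lower index.  Idempotent for a fixed config."""
    if config is None:
        config = FusionConfig()
    scores = np.asarray(scores, dtype=float)
    if len(scores) != fused.dim:
        raise ValueError("scores must align with the fused vector")
    k = min(config.select_n, fused.dim)
    order = np.lexsort((np.arange(len(scores)), -scores))  # score desc, index asc
    keep = np.sort(order[:k])
    base = fused.selected_indices if fused.selected_indices is not None else np.arange(fused.dim)
    return FusedVector(
        values=fused.values[keep],
        selected_indices=np.asarray(base)[keep],
        entropy_scores=scores[keep],
    )
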