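"""Gray-level histograms and Kapur's maximum-entropy thresholding objective.

Kapur's criterion picks gray-level cut points that maximize the sum of the
Shannon entropies of the intensity classes they induce.  A threshold vector
``T = (t_1, ..., t_{n-1})`` splits the gray range ``[0, L)`` into the
half-open classes ``[0, t_1), [t_1, t_2), ..., [t_{n-1}, L)`` (a threshold
assigns its own level to the upper class).  For class ``C`` with probability
mass ``w = sum_{s in C} p_s`` the class entropy is

    H(C) = -sum_{s in C, p_s > 0} (p_s / w) * ln(p_s / w)

in nats, and the objective is ``sum_C H(C)``, to be maximized.  Classes with
zero mass contribute zero entropy by convention.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Histogram",
    "ThresholdVector",
    "KapurScore",
    "compute_histogram",
    "class_entropy",
    "kapur_objective",
    "exhaustive_best_thresholds",
    "KapurTable",
]

DEFAULT_LEVELS = 256

# classes whose probability mass falls below this are treated as empty
# (entropy 0); guards the cumulative-sum table against cancellation noise
MASS_EPS = 1e-12


@dataclass(frozen=True)
class Histogram:
    """Gray-level probability distribution of an image.

    Attributes
    ----------
    counts : ndarray of int, shape (L,)
        Pixel count per gray level.
    probs : ndarray of float, shape (L,)
        ``counts / total_pixels``; sums to 1.
    total_pixels : int
        Number of pixels counted.
    """

    counts: np.ndarray
    probs: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise ValueError("histogram must cover at least one pixel")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def levels(self) -> int:
        return len(self.counts)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Histogram":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total == 0:
            raise ValueError("empty histogram")
        return cls(counts=counts, probs=counts / total, total_pixels=total)

    @classmethod
    def from_probs(cls, probs: np.ndarray, total_pixels: int = 1_000_000) -> "Histogram":
        """Build from a probability vector (counts are a scaled surrogate)."""
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0):
            raise ValueError("negative probabilities")
        s = probs.sum()
        if s <= 0:
            raise ValueError("probabilities sum to zero")
        probs = probs / s
        counts = np.round(probs * total_pixels).astype(np.int64)
        return cls(counts=counts, probs=probs, total_pixels=total_pixels)

    def to_json(self) -> str:
        return json.dumps({"levels": self.levels, "counts": self.counts.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Histogram":
        obj = json.loads(text)
        counts = np.asarray(obj["counts"], dtype=np.int64)
        if len(counts) != obj["levels"]:
            raise ValueError("level count mismatch in serialized histogram")
        return cls.from_counts(counts)


@dataclass(frozen=True)
class ThresholdVector:
    """Strictly increasing gray-level cut points defining ``n_classes`` classes."""

    thresholds: tuple[int, ...]
    levels: int = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 1:
            raise ValueError("need at least one threshold")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {t}")
        if t[0] < 1 or t[-1] > self.levels - 1:
            raise ValueError(f"thresholds must lie in [1, {self.levels - 1}]: {t}")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1

    def class_bounds(self) -> list[tuple[int, int]]:
        """Half-open ``[lo, hi)`` gray-level interval per class."""
        edges = (0, *self.thresholds, self.levels)
        return list(zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class KapurScore:
    """Kapur objective value with its per-class decomposition."""

    value: float
    per_class_entropies: np.ndarray
    class_masses: np.ndarray


def compute_histogram(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> Histogram:
    """Count gray levels of a 2-D image into an L-bin histogram.

    Raises on an empty image or pixels outside ``[0, levels)``.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    flat = np.round(image).astype(np.int64).ravel()
    if flat.min() < 0 or flat.max() > levels - 1:
        raise ValueError(
            f"pixel values outside [0, {levels - 1}]: range "
            f"[{flat.min()}, {flat.max()}]"
        )
    counts = np.bincount(flat, minlength=levels)
    return Histogram.from_counts(counts)


def class_entropy(hist: Histogram, lo: int, hi: int) -> tuple[float, float]:
    """Entropy (nats) and probability mass of the gray-level class ``[lo, hi]``.

    Inclusive bounds; a zero-mass class has entropy 0 by convention.
    """
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    if lo < 0 or hi > hist.levels - 1:
        raise ValueError("class bounds outside gray range")
    p = hist.probs[lo : hi + 1]
    mass = float(p.sum())
    if mass <= MASS_EPS:
        return 0.0, mass
    q = p[p > 0] / mass
    entropy = float(-(q * np.log(q)).sum())
    return entropy, mass


def kapur_objective(hist: Histogram, T: ThresholdVector) -> KapurScore:
    """Sum of class entropies induced by threshold vector ``T``."""
    if T.levels != hist.levels:
        raise ValueError("threshold vector and histogram disagree on L")
    ents, masses = [], []
    for lo, hi in T.class_bounds():
        e, w = class_entropy(hist, lo, hi - 1)
        ents.append(e)
        masses.append(w)
    ents = np.asarray(ents)
    masses = np.asarray(masses)
    return KapurScore(value=float(ents.sum()), per_class_entropies=ents, class_masses=masses)


class KapurTable:
    """Precomputed interval-entropy table for fast repeated Kapur evaluation.

    ``entropy[a, b]`` is the entropy of the half-open class ``[a, b)``.
    Built once per histogram; evaluating a threshold vector is then O(n).
    """

    def __init__(self, hist: Histogram):
        self.hist = hist
        L = hist.levels
        p = hist.probs.astype(np.longdouble)  # extended precision: the
        # cumulative-sum differences below cancel catastrophically in float64
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        cp = np.concatenate([[0.0], np.cumsum(p)])  # cp[b] = sum p[0:b]
        cs = np.concatenate([[0.0], np.cumsum(plogp)])
        # interval [a, b): mass w = cp[b]-cp[a]; entropy = ln w - (cs[b]-cs[a])/w
        w = cp[None, :] - cp[:, None]
        s = cs[None, :] - cs[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(w > MASS_EPS, np.log(np.maximum(w, MASS_EPS)) - s / np.maximum(w, MASS_EPS), 0.0)
        ent[w <= MASS_EPS] = 0.0
        # cancellation in the cumulative sums cannot push an entropy outside
        # its analytic range [0, ln(interval width)]
        idx = np.arange(L + 1)
        width = np.maximum(idx[None, :] - idx[:, None], 1)
        ent = np.clip(ent, 0.0, np.log(width))
        self._mass = w.astype(float)  # (L+1, L+1)
        ent = ent.astype(float)
        self._entropy = ent
        self.levels = L

    def entropy(self, a: int, b: int) -> float:
        return float(self._entropy[a, b])

    def value(self, thresholds) -> float:
        edges = (0, *map(int, thresholds), self.levels)
        return float(sum(self._entropy[a, b] for a, b in zip(edges[:-1], edges[1:])))

    def n_empty_classes(self, thresholds) -> int:
        edges = (0, *map(int, thresholds), self.levels)
        return int(sum(self._mass[a, b] <= MASS_EPS for a, b in zip(edges[:-1], edges[1:])))


def exhaustive_best_thresholds(
    hist: Histogram, n_classes: int
) -> tuple[ThresholdVector, KapurScore]:
    """Globally optimal thresholds by full enumeration (oracle).

    Feasible for ``n_classes`` in {2, 3, 4}; ties broken by the
    lexicographically smallest threshold vector.
    """
    if n_classes not in (2, 3, 4):
        raise ValueError("exhaustive search supported only for n_classes in {2, 3, 4}")
    L = hist.levels
    table = KapurTable(hist)
    E = table._entropy
    cand = np.arange(1, L)

    if n_classes == 2:
        scores = E[0, cand] + E[cand, L]
        best = int(np.argmax(scores))
        bt = (int(cand[best]),)
    elif n_classes == 3:
        best_val = -np.inf
        bt = None
        for t1 in range(1, L - 1):
            t2 = np.arange(t1 + 1, L)
            scores = E[0, t1] + E[t1, t2] + E[t2, L]
            j = int(np.argmax(scores))
            if scores[j] > best_val:
                best_val = float(scores[j])
                bt = (t1, int(t2[j]))
    else:
        best_val = -np.inf
        bt = None
        for t1 in range(1, L - 2):
            t2 = np.arange(t1 + 1, L - 1)
            # grid over (t2, t3) with t3 > t2
            t3 = np.arange(t1 + 2, L)
            grid = (
                E[0, t1]
                + E[t1, t2][:, None]
                + E[np.ix_(t2, t3)]
                + E[t3, L][None, :]
            )
            valid = t3[None, :] > t2[:, None]
            grid = np.where(valid, grid, -np.inf)
            j = int(np.argmax(grid))
            r, c = divmod(j, grid.shape[1])
            if grid[r, c] > best_val:
                best_val = float(grid[r, c])
                bt = (t1, int(t2[r]), int(t3[c]))
    T = ThresholdVector(thresholds=bt, levels=L)
    return T, kapur_objective(hist, T)
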