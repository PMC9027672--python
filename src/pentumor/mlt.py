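"""Multilevel Otsu thresholding: histogram, objective, oracle, label maps.

K thresholds ``t_1 < ... < t_K`` partition the gray-level axis
``[0, L-1]`` into K+1 classes, class ``u`` covering the integer levels
``[t_u, t_{u+1} - 1]`` with implicit ``t_0 = 0`` and ``t_{K+1} = L``.
The Otsu criterion scores a threshold set by its between-class variance

    F(t_1, ..., t_K) = sum_u A_u (eta_u - mu)^2

where ``A_u`` is the probability mass of class ``u``, ``eta_u`` its mean
intensity and ``mu`` the global mean.  Maximizing F is equivalent to
minimizing the pooled within-class variance (the two always sum to the
total variance — a property used as a correctness test).

:func:`exhaustive_mlt` enumerates all threshold tuples and is the exact
oracle at small scale; larger searches go through the swarm optimizers in
:mod:`pentumor.optimizers`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantoms import GrayImage


class ThresholdError(ValueError):
    """Raised for invalid threshold sets or histograms."""


class EnumerationGuardError(RuntimeError):
    """Exhaustive enumeration would be too large; use the EPO search instead."""


@dataclass
class Histogram:
    """Gray-level counts ``h_u`` and probabilities ``P_u = h_u / N_p``."""

    counts: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.shape[0] != self.levels:
            raise ThresholdError(
                f"counts must be a length-{self.levels} vector, got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ThresholdError("histogram counts must be nonnegative")
        self.counts = counts.astype(np.int64)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        n = self.n_pixels
        if n == 0:
            raise ThresholdError("empty histogram has no probabilities")
        return self.counts / n

    def occupied_levels(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class ThresholdSet:
    """K strictly increasing integer thresholds, each in ``[1, L-1]``."""

    thresholds: tuple[int, ...]
    levels: int

    def __post_init__(self) -> None:
        ts = tuple(int(t) for t in self.thresholds)
        if len(ts) == 0:
            raise ThresholdError("at least one threshold is required")
        if any(t < 1 or t > self.levels - 1 for t in ts):
            raise ThresholdError(
                f"thresholds must lie in [1, {self.levels - 1}], got {ts}"
            )
        if any(a >= b for a, b in zip(ts, ts[1:])):
            raise ThresholdError(f"thresholds must be strictly increasing, got {ts}")
        object.__setattr__(self, "thresholds", ts)

    @property
    def k(self) -> int:
        return len(self.thresholds)

    def class_edges(self) -> list[tuple[int, int]]:
        """Closed-open level ranges ``[t_u, t_{u+1})`` of the K+1 classes."""
        edges = [0, *self.thresholds, self.levels]
        return list(zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class OtsuScore:
    """Between-class variance and its ingredients for one threshold set."""

    between_class_variance: float
    class_probs: tuple[float, ...]
    class_means: tuple[float, ...]
    global_mean: float


def compute_histogram(
    image: GrayImage | np.ndarray, levels: Optional[int] = None
) -> Histogram:
    """Count occurrences of each gray level.

    Accepts a :class:`GrayImage` (levels taken from the image) or any 2-D
    integer array with an explicit ``levels`` count.
    """
    if isinstance(image, GrayImage):
        pixels, levels = image.pixels, image.levels
    else:
        pixels = np.asarray(image)
        if levels is None:
            raise ThresholdError("levels must be given for raw-array input")
        if pixels.min() < 0 or pixels.max() >= levels:
            raise ThresholdError(
                f"pixel values must lie in [0, {levels - 1}]"
            )
    counts = np.bincount(pixels.ravel().astype(np.int64), minlength=levels)
    return Histogram(counts, levels)


def total_variance(hist: Histogram) -> float:
    """Total intensity variance ``sum_v P_v (v - mu)^2`` of the histogram."""
    p = hist.probabilities
    v = np.arange(hist.levels)
    mu = float(np.dot(p, v))
    return float(np.dot(p, (v - mu) ** 2))


def otsu_objective(hist: Histogram, ts: ThresholdSet) -> OtsuScore:
    """Between-class variance F of a threshold set on a histogram.

    Empty classes (zero probability mass) contribute 0 to F and report a
    class mean of 0, so the objective stays defined for any thresholds an
    optimizer might propose.
    """
    if ts.levels != hist.levels:
        raise ThresholdError(
            f"threshold levels ({ts.levels}) do not match histogram ({hist.levels})"
        )
    p = hist.probabilities
    v = np.arange(hist.levels)
    mu = float(np.dot(p, v))
    probs, means, f = [], [], 0.0
    for lo, hi in ts.class_edges():
        a = float(p[lo:hi].sum())
        if a > 0.0:
            eta = float(np.dot(p[lo:hi], v[lo:hi])) / a
            f += a * (eta - mu) ** 2
        else:
            eta = 0.0
        probs.append(a)
        means.append(eta)
    return OtsuScore(f, tuple(probs), tuple(means), mu)


def exhaustive_mlt(hist: Histogram, k: int) -> tuple[ThresholdSet, OtsuScore]:
    """Exact multilevel-Otsu search by enumerating all K-tuples.

    Ties are broken by the lexicographically smallest tuple.  Guarded:
    refuses enumerations above 10^7 candidate tuples.
    """
    if k < 1:
        raise ThresholdError(f"k must be >= 1, got {k}")
    occupied = hist.occupied_levels()
    if k > occupied - 1:
        raise ThresholdError(
            f"k={k} exceeds occupied levels - 1 ({occupied - 1})"
        )
    n_tuples = math.comb(hist.levels - 1, k)
    if n_tuples > 10**7:
        raise EnumerationGuardError(
            f"{n_tuples} candidate threshold tuples exceed the exhaustive "
            "guard (1e7); use the EPO search instead"
        )
    p = hist.probabilities
    v = np.arange(hist.levels)
    mu = float(np.dot(p, v))
    # prefix sums make each candidate an O(K) evaluation
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cvp = np.concatenate([[0.0], np.cumsum(p * v)])

    best_ts: Optional[tuple[int, ...]] = None
    best_f = -np.inf
    for ts in itertools.combinations(range(1, hist.levels), k):
        edges = (0, *ts, hist.levels)
        f = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            a = cp[hi] - cp[lo]
            if a > 0.0:
                eta = (cvp[hi] - cvp[lo]) / a
                f += a * (eta - mu) ** 2
        if f > best_f:  # strict: first (lexicographically smallest) max wins
            best_f = f
            best_ts = ts
    assert best_ts is not None
    ts_set = ThresholdSet(best_ts, hist.levels)
    return ts_set, otsu_objective(hist, ts_set)


def apply_thresholds(image: GrayImage | np.ndarray, ts: ThresholdSet) -> np.ndarray:
    """Map each pixel to its class index in ``[0, K]``.

    A pixel of value g lands in class k where ``t_k <= g <= t_{k+1} - 1``.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if isinstance(image, GrayImage) and image.levels != ts.levels:
        raise ThresholdError(
            f"threshold levels ({ts.levels}) do not match image ({image.levels})"
        )
    return np.digitize(pixels, ts.thresholds, right=False)


def decode_thresholds(vector: np.ndarray, levels: int) -> ThresholdSet:
    """Decode a real optimizer vector into a valid threshold set.

    The K reals are sorted, rounded to integers in ``[1, L-1]``, and
    collisions are pushed up by one (then down from the top if the upper
    bound is hit), yielding strictly increasing thresholds.
    """
    vals = np.sort(np.asarray(vector, dtype=float))
    ts = [int(np.clip(round(x), 1, levels - 1)) for x in vals]
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + 1
    for i in range(len(ts) - 1, -1, -1):
        cap = levels - 1 - (len(ts) - 1 - i)
        if ts[i] > cap:
            ts[i] = cap
    for i in range(1, len(ts)):  # re-sweep after capping
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + 1
    return ThresholdSet(tuple(ts), levels)
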