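"""Entropy and Jensen-Shannon dissimilarity on 16-pattern epiallele distributions.

A 4-CpG epiallele observed on a sequenced fragment takes one of 16 binary
methylation patterns.  Each locus in each sample therefore yields a
probability distribution over 16 patterns, and the dissimilarity between two
samples at a locus is the square root of the Jensen-Shannon divergence of the
two distributions.  With logarithms in base 2 the JS divergence is bounded by
[0, 1]; its square root (by the theorem of Fuglede and Topsoe) is a metric on
distributions, also in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedDistributionError

__all__ = [
    "PatternDistribution",
    "entropy",
    "js_divergence",
    "jsd",
    "DEFAULT_EPSILON",
]

#: Default pseudocount added to each pattern probability before renormalising.
#: Keeps every probability strictly positive so the logarithm is defined.
DEFAULT_EPSILON = 6.25e-3

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class PatternDistribution:
    """A normalised probability vector over the 16 epiallele patterns.

    Attributes
    ----------
    probs
        Length-16 vector summing to 1 (within 1e-12).
    source_depth
        Number of fragments the distribution was estimated from.
    """

    probs: np.ndarray
    source_depth: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(probs < -1e-15) or abs(probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError("probs must be non-negative and sum to 1")


def _as_probs(p: PatternDistribution | np.ndarray) -> np.ndarray:
    if isinstance(p, PatternDistribution):
        return p.probs
    return np.asarray(p, dtype=float)


def entropy(p: PatternDistribution | np.ndarray) -> float:
    """Shannon entropy in bits, with the 0*log(0) := 0 convention.

    For a 16-pattern distribution the result lies in [0, 4] bits: 0 for a
    point mass, 4 for the uniform mixture.

    Raises
    ------
    ValueError
        If the vector is not normalised to 1 within 1e-9.
    """
    probs = _as_probs(p)
    if abs(probs.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"distribution not normalised: sum={probs.sum()!r}")
    nz = probs[probs > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(
    p: PatternDistribution | np.ndarray, q: PatternDistribution | np.ndarray
) -> float:
    """Jensen-Shannon divergence JS(p, q) = H((p+q)/2) - (H(p)+H(q))/2 in bits.

    Symmetric, zero iff ``p == q``, and bounded by 1 for base-2 logarithms.
    The result is clamped to [0, 1] to absorb rounding error of order 1e-16.
    """
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ValueError(f"length mismatch: {pv.shape} vs {qv.shape}")
    js = entropy(0.5 * (pv + qv)) - 0.5 * (entropy(pv) + entropy(qv))
    return float(min(1.0, max(0.0, js)))


def pattern_distribution(
    counts: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> PatternDistribution:
    """Estimate the pattern distribution from a 16-vector of read counts.

    The raw frequencies ``p_i = counts_i / depth`` receive a pseudocount and
    are renormalised: ``p'_i = (p_i + epsilon) / (1 + 16 * epsilon)``, so the
    result sums to 1 exactly and, for ``epsilon > 0``, has no zero entries.

    Raises
    ------
    UndefinedDistributionError
        If the counts sum to zero.
    ValueError
        If ``epsilon`` is negative.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum()
    if depth <= 0:
        raise UndefinedDistributionError("cannot form a distribution at depth 0")
    raw = counts / depth
    probs = (raw + epsilon) / (1.0 + counts.size * epsilon)
    return PatternDistribution(probs=probs, source_depth=int(depth))


def jsd(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Jensen-Shannon dissimilarity between two pattern count vectors.

    ``sqrt(JS(P_a, P_b))`` where each distribution is the pseudocount-adjusted
    frequency vector of its counts.  Symmetric, in [0, 1], and a metric.
    """
    pa = pattern_distribution(counts_a, epsilon)
    pb = pattern_distribution(counts_b, epsilon)
    return float(np.sqrt(js_divergence(pa, pb)))
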