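"""Heterogeneity indices on abundance distributions.

Pure computation layer, independent of any raster context. A window
sample (a multiset of scalar values, or of fixed-length tuples in the
multi-layer case) is first reduced to an :class:`AbundanceDistribution`;
the indices then operate on the relative abundances, and Rao's quadratic
entropy additionally on a :class:`DistanceMatrix` of pairwise distances
between the distinct values.

All entropies use the natural logarithm (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .exceptions import (
    EmptySampleError,
    MetricMismatchError,
    ParameterError,
    ShapeMismatchError,
)

#: |alpha - 1| below this routes Renyi/Hill through the Shannon limit,
#: avoiding catastrophic cancellation in 1/(1-alpha).
ALPHA_ONE_TOL = 1e-9

SCALAR_METRICS = ("absolute-difference",)
TUPLE_METRICS = ("euclidean", "manhattan")


@dataclass(frozen=True)
class AbundanceDistribution:
    """Distinct observed values with their relative abundances.

    ``values`` is a 1-D array of scalars in ascending order, or a 2-D
    ``(k, n_layers)`` array of tuple-valued observations in ascending
    lexicographic order. ``abundances`` are the matching relative
    abundances p_i (> 0, summing to 1), and ``n_obs`` the number of valid
    observations the distribution was built from.
    """

    values: np.ndarray
    abundances: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        p = np.asarray(self.abundances, dtype=np.float64)
        if values.ndim not in (1, 2):
            raise ValueError("values must be 1-D (scalar) or 2-D (tuple)")
        if len(values) != len(p):
            raise ValueError("values and abundances length mismatch")
        if len(values) == 0:
            raise EmptySampleError("no valid observations")
        if np.any(p <= 0):
            raise ValueError("all abundances must be > 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"abundances sum to {p.sum()!r}, not 1")
        if not (1 <= len(values) <= self.n_obs):
            raise ValueError("richness must lie in [1, n_obs]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "abundances", p)

    @property
    def richness(self) -> int:
        """Number of distinct values."""
        return len(self.values)

    @property
    def is_tuple_valued(self) -> bool:
        return self.values.ndim == 2


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between the distinct values of a
    paired :class:`AbundanceDistribution`, indexed consistently."""

    entries: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        d = np.asarray(self.entries, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.diagonal(d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.array_equal(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "entries", d)


def relative_abundances(
    sample: Union[np.ndarray, "list"],
) -> AbundanceDistribution:
    """Reduce a window sample to its distinct values and abundances.

    ``sample`` is a 1-D array of scalar observations, or a 2-D
    ``(n_obs, n_layers)`` array of tuple observations. Values are sorted
    ascending (tuples lexicographically) so downstream results do not
    depend on input order.
    """
    arr = np.asarray(sample)
    if arr.ndim not in (1, 2):
        raise ValueError("sample must be 1-D (scalar) or 2-D (n_obs, n_layers)")
    if arr.shape[0] == 0:
        raise EmptySampleError("no valid observations")
    if arr.ndim == 1:
        values, counts = np.unique(arr, return_counts=True)
    else:
        values, counts = np.unique(arr, axis=0, return_counts=True)
    n_obs = int(arr.shape[0])
    return AbundanceDistribution(
        values=values, abundances=counts / n_obs, n_obs=n_obs
    )


def shannon(dist: AbundanceDistribution) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    p = dist.abundances
    return float(-(p @ np.log(p)))


def renyi(dist: AbundanceDistribution, alpha: float) -> float:
    """Renyi generalized entropy of order ``alpha`` >= 0, in nats.

    ``alpha = 0`` gives log-richness; ``alpha`` within :data:`ALPHA_ONE_TOL`
    of 1 is routed to the Shannon limit; ``alpha = 2`` equals
    ``ln(1/D)`` with D the Simpson dominance.
    """
    alpha = float(alpha)
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    if abs(alpha - 1.0) <= ALPHA_ONE_TOL:
        return shannon(dist)
    if alpha == 0.0:
        return float(np.log(dist.richness))
    # ln(sum p_i^alpha) in log space: stable for large alpha.
    log_sum = logsumexp(alpha * np.log(dist.abundances))
    return float(log_sum / (1.0 - alpha))


def simpson_dominance(dist: AbundanceDistribution) -> float:
    """Simpson dominance D = sum p_i^2: the probability that two draws
    with replacement share a value."""
    p = dist.abundances
    return float(p @ p)


def hill(dist: AbundanceDistribution, q: float) -> float:
    """Hill number of order ``q`` >= 0: the effective number of equally
    abundant classes, exp of the Renyi entropy of the same order."""
    q = float(q)
    if q < 0:
        raise ParameterError(f"q must be >= 0, got {q}")
    return float(np.exp(renyi(dist, q)))


def build_distance_matrix(
    dist: AbundanceDistribution, metric: str = "absolute-difference"
) -> DistanceMatrix:
    """Pairwise distance matrix between the distinct values of ``dist``.

    ``absolute-difference`` applies to scalar values; ``euclidean`` and
    ``manhattan`` to tuple (multi-layer) values.
    """
    values = dist.values
    if metric in SCALAR_METRICS:
        if dist.is_tuple_valued:
            raise MetricMismatchError(
                f"scalar metric {metric!r} requested on tuple values"
            )
        v = values.astype(np.float64)
        entries = np.abs(v[:, None] - v[None, :])
    elif metric in TUPLE_METRICS:
        if not dist.is_tuple_valued:
            raise MetricMismatchError(
                f"tuple metric {metric!r} requested on scalar values"
            )
        v = values.astype(np.float64)
        entries = cdist(v, v, metric="cityblock" if metric == "manhattan" else "euclidean")
        # cdist output is symmetric up to rounding; enforce exactly.
        entries = np.minimum(entries, entries.T)
        np.fill_diagonal(entries, 0.0)
    else:
        raise ParameterError(
            f"unknown metric {metric!r}; choose from "
            f"{SCALAR_METRICS + TUPLE_METRICS}"
        )
    return DistanceMatrix(entries=entries, metric_name=metric)


def rao_q(dist: AbundanceDistribution, dmat: DistanceMatrix) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    The expected distance between two observations drawn at random with
    replacement; equals the all-pixel-pairs formulation
    ``sum(d) / n_obs**2`` exactly.
    """
    p = dist.abundances
    if dmat.entries.shape[0] != len(p):
        raise ShapeMismatchError(
            f"distance matrix dimension {dmat.entries.shape[0]} does not "
            f"match richness {len(p)}"
        )
    return float(p @ dmat.entries @ p)


def rao_q_from_sample(
    sample: np.ndarray, metric: str = "absolute-difference"
) -> float:
    """Convenience: Rao's Q straight from a window sample."""
    dist = relative_abundances(sample)
    return rao_q(dist, build_distance_matrix(dist, metric))


def rao_q_multilayer(
    layer_samples: "list[np.ndarray]", metric: str = "euclidean"
) -> float:
    """Rao's Q over aligned samples from several layers.

    Each element of ``layer_samples`` holds the values of one layer at
    the same pixel positions; pixels are combined into tuple-valued
    observations before the distance matrix is built. With a single
    layer and the absolute-difference metric this reduces exactly to the
    single-layer :func:`rao_q`.
    """
    if not layer_samples:
        raise EmptySampleError("no layers given")
    arrays = [np.asarray(s).ravel() for s in layer_samples]
    n = arrays[0].shape[0]
    for a in arrays:
        if a.shape[0] != n:
            raise ShapeMismatchError("layer samples have different lengths")
    if n == 0:
        raise EmptySampleError("no valid observations")
    if len(arrays) == 1 and metric in SCALAR_METRICS:
        return rao_q_from_sample(arrays[0], metric)
    observations = np.stack(arrays, axis=1)  # (n_obs, n_layers)
    dist = relative_abundances(observations)
    return rao_q(dist, build_distance_matrix(dist, metric))
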