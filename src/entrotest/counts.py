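"""Ordered categorical data: probability vectors, count tables, and the
synthetic probability profiles used in the simulation study.

Category order is part of the data model.  The discrete Fisher information
depends on adjacency of categories, so every operation here preserves order;
nothing is ever sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "ProbabilityVector",
    "CountTable",
    "mle_proportions",
    "linear_model",
    "one_almost_zero_model",
    "half_and_half_model",
    "sample_counts",
    "collapse_categories",
    "EPS0_DEFAULT",
]

#: Default near-zero cell for the One-Almost-Zero profile: the double-precision
#: machine epsilon, the smallest eps with 1 + eps > 1.
EPS0_DEFAULT = 2.220446e-16

_SUM_TOL = 1e-12


@dataclass(frozen=True, eq=False)
class ProbabilityVector:
    """An ordered vector of category probabilities.

    Parameters
    ----------
    values
        Probabilities ``p_1, ..., p_k``; non-negative, summing to one
        (within 1e-12).
    labels
        Optional ordered category names, one per probability.
    """

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __init__(self, values: Sequence[float], labels: Sequence[str] | None = None):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("a probability vector needs k >= 2 ordered entries")
        if np.any(arr < 0):
            raise InvalidInputError("probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise InvalidInputError(f"probabilities must sum to 1, got {arr.sum()!r}")
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != arr.size:
                raise InvalidInputError("labels length must match number of categories")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True, eq=False)
class CountTable:
    """Ordered non-negative integer counts from one multinomial sample."""

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __init__(self, counts: Sequence[int], labels: Sequence[str] | None = None):
        arr = np.asarray(counts)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("a count table needs k >= 2 ordered entries")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.asarray(arr, dtype=float)
            if np.any(rounded != np.floor(rounded)):
                raise InvalidInputError("counts must be integers")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise InvalidInputError("counts must be non-negative")
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != arr.size:
                raise InvalidInputError("labels length must match number of categories")
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        """Total number of trials."""
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return int(self.counts.size)

    def proportions(self) -> ProbabilityVector:
        """Maximum-likelihood proportions ``N/n`` (see :func:`mle_proportions`)."""
        return mle_proportions(self)


def mle_proportions(counts: CountTable) -> ProbabilityVector:
    """Maximum-likelihood estimator of the multinomial probabilities.

    The MLE of ``p`` under Mult(n, p) is the vector of observed proportions
    ``N_l / n``.  Zero counts yield zero probabilities, which is allowed.

    Raises
    ------
    InvalidInputError
        If all counts are zero (n = 0).
    """
    n = counts.n
    if n < 1:
        raise InvalidInputError("cannot form proportions from an all-zero count table")
    return ProbabilityVector(counts.counts / n, labels=counts.labels)


def linear_model(k: int) -> ProbabilityVector:
    """Linearly increasing profile ``p_l = 2 l / (k (k + 1))``."""
    if k < 2:
        raise InvalidInputError("linear model requires k >= 2")
    ell = np.arange(1, k + 1, dtype=float)
    return ProbabilityVector(2.0 * ell / (k * (k + 1)))


def one_almost_zero_model(k: int, eps0: float = EPS0_DEFAULT) -> ProbabilityVector:
    """Near-uniform profile with one almost-empty cell.

    ``p_l = 1/k`` for ``l <= k-2``, ``p_{k-1} = eps0`` and ``p_k = 2/k - eps0``.
    The default ``eps0`` is the double-precision machine epsilon, giving one
    category that is populated with essentially zero probability.
    """
    if k < 3:
        raise InvalidInputError("one-almost-zero model requires k >= 3")
    if not (0.0 < eps0 < 2.0 / k):
        raise InvalidInputError(f"eps0 must lie in (0, 2/k) = (0, {2.0 / k!r})")
    p = np.full(k, 1.0 / k)
    p[k - 2] = eps0
    p[k - 1] = 2.0 / k - eps0
    return ProbabilityVector(p)


def half_and_half_model(k: int, eps: float) -> ProbabilityVector:
    """Two-level profile: ``(1 + eps)/k`` on the first half, ``(1 - eps)/k`` on
    the second.  ``eps = 0`` recovers the uniform distribution.

    Only even ``k`` is meaningful; odd ``k`` raises rather than guessing how to
    split the middle category.
    """
    if k < 2 or k % 2 != 0:
        raise InvalidInputError("half-and-half model requires even k >= 2")
    if not (0.0 <= eps < 1.0):
        raise InvalidInputError("eps must lie in [0, 1)")
    p = np.empty(k)
    p[: k // 2] = (1.0 + eps) / k
    p[k // 2:] = (1.0 - eps) / k
    return ProbabilityVector(p)


def sample_counts(
    p: ProbabilityVector,
    n: int,
    seed: int | np.random.Generator,
) -> CountTable:
    """Draw one exact multinomial sample Mult(n, p).

    Uses numpy's exact multinomial sampler (sequential binomials); a normal
    approximation would be wrong in the tails, which matter when some
    ``n * p_l`` is far below one.

    ``seed`` is mandatory: either an integer or an existing Generator
    (no hidden global state).
    """
    if n < 1:
        raise InvalidInputError("sample size n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, p.values)
    return CountTable(counts, labels=p.labels)


def collapse_categories(
    counts: CountTable, groups: Sequence[Sequence[int]]
) -> CountTable:
    """Merge adjacent categories into blocks, preserving order.

    ``groups`` is an ordered partition of the 0-based category indices into
    contiguous blocks, e.g. ``[[0, 1], [2], [3, 4]]``.  Contiguity is enforced
    because the Fisher information reads adjacency off the category order:
    merging non-neighbouring categories would scramble it.
    """
    flat: list[int] = []
    for block in groups:
        block = list(block)
        if not block:
            raise InvalidInputError("empty block in category partition")
        if block != list(range(block[0], block[0] + len(block))):
            raise InvalidInputError(f"block {block} is not contiguous ascending")
        flat.extend(block)
    if flat != list(range(counts.k)):
        raise InvalidInputError(
            "blocks must form an ordered partition of all category indices"
        )
    merged = np.array([int(counts.counts[list(b)].sum()) for b in groups])
    labels = None
    if counts.labels is not None:
        labels = tuple("+".join(counts.labels[i] for i in b) for b in groups)
    return CountTable(merged, labels=labels)
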