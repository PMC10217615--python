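"""Plug-in entropy functionals for discrete distributions.

Four descriptors of a probability vector p over k ordered categories:

* Shannon entropy      ``H_S = -sum p_l log p_l``
* Tsallis entropy      ``H_T(q) = sum (p_l - p_l^q) / (q - 1)``, q != 1
* Renyi entropy        ``H_R(q) = log(sum p_l^q) / (1 - q)``, q > 0, q != 1
* Fisher information   ``H_F = F0 * sum (sqrt(p_{l+1}) - sqrt(p_l))^2``

All logarithms are natural; raw entropies are in nats.  The normalized
variants (divide Shannon/Renyi by log k, multiply Tsallis by
``(q-1)/(1-k^{1-q})``) are base-invariant and lie in [0, 1], equal to 1
exactly at the uniform distribution.  Fisher information is reported as
defined, with renormalization constant F0 (default 4); it is zero at the
uniform distribution and depends on category order.  Conventions
``0 log 0 := 0`` and ``0^q := 0`` (q > 0) apply element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import ProbabilityVector
from .exceptions import InvalidInputError, InvalidOrderError

__all__ = [
    "EntropySpec",
    "shannon",
    "tsallis",
    "renyi",
    "fisher_information",
    "entropy",
    "tsallis_normalization",
]

_FAMILIES = ("shannon", "tsallis", "renyi", "fisher")


@dataclass(frozen=True)
class EntropySpec:
    """Which entropy functional to compute, and under which conventions.

    Attributes
    ----------
    family
        One of ``shannon``, ``tsallis``, ``renyi``, ``fisher``.
    q
        Entropy order; required for Tsallis (q != 1) and Renyi (q > 0, q != 1).
    normalized
        Rescale to [0, 1] (no-op for Fisher, which carries its own F0 scale).
    fisher_constant
        The renormalization constant F0 in the Fisher functional.
    fisher_variance_mode
        ``delta`` (default): delta-method variance from the scalar gradient.
        ``paper``: the published closed-form transcribed verbatim, kept for
        comparison only (see docs/methods.md).
    renyi_variance_convention
        ``power_sum`` (default): the variance attached to a Renyi law is the
        variance of the power sum ``S = sum p^q``.  ``delta``: the variance of
        the entropy itself obtained by the delta method on log S.
    """

    family: str
    q: float | None = None
    normalized: bool = False
    fisher_constant: float = 4.0
    fisher_variance_mode: str = "delta"
    renyi_variance_convention: str = "power_sum"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidInputError(
                f"unknown entropy family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "tsallis":
            if self.q is None or self.q == 1.0:
                raise InvalidOrderError("tsallis requires an order q != 1")
        elif self.family == "renyi":
            if self.q is None or self.q <= 0.0 or self.q == 1.0:
                raise InvalidOrderError("renyi requires an order q > 0, q != 1")
        if self.fisher_constant <= 0:
            raise InvalidInputError("fisher_constant F0 must be positive")
        if self.fisher_variance_mode not in ("delta", "paper"):
            raise InvalidInputError("fisher_variance_mode must be 'delta' or 'paper'")
        if self.renyi_variance_convention not in ("power_sum", "delta"):
            raise InvalidInputError(
                "renyi_variance_convention must be 'power_sum' or 'delta'"
            )

    @property
    def label(self) -> str:
        """Short display name, e.g. ``HS``, ``HT1/2``, ``HR1/3``, ``HF``."""
        if self.family == "shannon":
            return "HS"
        if self.family == "fisher":
            return "HF"
        prefix = "HT" if self.family == "tsallis" else "HR"
        from fractions import Fraction

        frac = Fraction(self.q).limit_denominator(100)
        return f"{prefix}{frac.numerator}/{frac.denominator}"


def _plogp(p: np.ndarray) -> np.ndarray:
    """Element-wise p log p with the 0 log 0 := 0 convention."""
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def shannon(p: ProbabilityVector, normalized: bool = False) -> float:
    """Shannon entropy in nats, or on [0, 1] if ``normalized``."""
    h = -float(_plogp(p.values).sum())
    if normalized:
        h /= np.log(p.k)
    return h


def tsallis_normalization(k: int, q: float) -> float:
    """Factor mapping raw Tsallis entropy onto [0, 1]: ``(q-1)/(1-k^{1-q})``.

    The reciprocal is the maximum of the raw functional, attained at the
    uniform distribution.
    """
    return (q - 1.0) / (1.0 - k ** (1.0 - q))


def tsallis(p: ProbabilityVector, q: float, normalized: bool = False) -> float:
    """Tsallis entropy of order q (q != 1)."""
    if q == 1.0:
        raise InvalidOrderError("tsallis order q must differ from 1")
    vals = p.values[p.values > 0]  # 0^q := 0, so zero cells contribute nothing
    h = float((vals - vals**q).sum()) / (q - 1.0)
    if normalized:
        h *= tsallis_normalization(p.k, q)
    return h


def renyi(p: ProbabilityVector, q: float, normalized: bool = False) -> float:
    """Renyi entropy of order q (q > 0, q != 1)."""
    if q <= 0.0 or q == 1.0:
        raise InvalidOrderError("renyi order q must be positive and differ from 1")
    vals = p.values
    s = float((vals[vals > 0] ** q).sum())
    h = np.log(s) / (1.0 - q)
    if normalized:
        h /= np.log(p.k)
    return float(h)


def fisher_information(p: ProbabilityVector, f0: float = 4.0) -> float:
    """Discrete Fisher information measure ``F0 sum (sqrt p_{l+1} - sqrt p_l)^2``.

    Order-sensitive: it sums squared increments of sqrt(p) over *adjacent*
    categories.  Zero at the uniform distribution.  Note the functional is not
    bounded by 1 for all p (an interior point mass exceeds it); no clamping is
    applied.
    """
    s = np.sqrt(p.values)
    return float(f0 * ((s[1:] - s[:-1]) ** 2).sum())


def entropy(p: ProbabilityVector, spec: EntropySpec) -> float:
    """Evaluate the functional described by ``spec`` at ``p``."""
    if spec.family == "shannon":
        return shannon(p, normalized=spec.normalized)
    if spec.family == "tsallis":
        return tsallis(p, spec.q, normalized=spec.normalized)
    if spec.family == "renyi":
        return renyi(p, spec.q, normalized=spec.normalized)
    return fisher_information(p, f0=spec.fisher_constant)
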