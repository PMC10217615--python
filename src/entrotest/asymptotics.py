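"""Asymptotic laws of plug-in entropies under multinomial sampling.

Let N ~ Mult(n, p) and p_hat = N/n.  Then sqrt(n)(p_hat - p) converges to a
multivariate normal with covariance ``Sigma_p = D_p - p p'``.  Propagating
each entropy functional through the multivariate delta method yields:

* Shannon, Tsallis(q) and Fisher information: normal limit laws, with
  variance ``a' Sigma_p a / n`` for the appropriate linearization vector a
  (``a_l = log p_l + 1`` for Shannon, ``a_l = (1 - q p_l^{q-1})/(q-1)`` for
  Tsallis, and the scalar gradient of the Fisher functional).
* Renyi(q): the power sum ``S = sum p_hat^q`` is asymptotically normal with
  mean ``mu* = sum p^q`` and variance
  ``sigma*^2 = (q^2/n)[sum p^{2q-1} - (sum p^q)^2]``; the entropy
  ``H = log(S)/(1-q)`` therefore follows the law of the logarithm of the
  absolute value of a normal variate ("log-power-normal"), not a normal law.

Zero cells: variance terms whose limit as p_l -> 0 is finite are evaluated at
that limit; terms that diverge (Renyi/Tsallis with 2q - 1 < 0) either raise or
— with the default zero-floor — drop the offending category from the variance
sums with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counts import ProbabilityVector
from .estimators import (
    EntropySpec,
    entropy,
    renyi,
    tsallis_normalization,
)
from .exceptions import DegenerateSupportError, InvalidInputError

__all__ = [
    "AsymptoticLaw",
    "multinomial_covariance",
    "entropy_gradient",
    "delta_covariance",
    "closed_form_delta_covariance",
    "fisher_paper_sigma_star",
    "asymptotic_law",
    "renyi_limit_density",
    "renyi_limit_cdf",
    "law_sampler",
    "ZERO_FLOOR_DEFAULT",
]

#: Probabilities below this floor are treated as structural zeros when a
#: variance term diverges at p -> 0.
ZERO_FLOOR_DEFAULT = 1e-10


@dataclass(frozen=True)
class AsymptoticLaw:
    """The limit distribution of one plug-in entropy estimate.

    ``shape`` is ``normal`` (Shannon, Tsallis, Fisher) or ``log_power_normal``
    (Renyi), in which case the power-sum parameters ``mu*``/``sigma*`` are
    carried alongside.  ``variance`` is on the reported scale (normalized if
    requested; for Renyi, per the chosen variance convention).
    """

    family: str
    shape: str
    mean: float
    variance: float
    n: int
    k: int
    normalized: bool = False
    q: float | None = None
    power_sum_mean: float | None = None
    power_sum_sd: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise InvalidInputError("asymptotic variance must be non-negative")
        if self.shape == "log_power_normal" and not self.degenerate:
            if self.power_sum_sd is None or self.power_sum_sd <= 0:
                raise InvalidInputError("log-power-normal law requires sigma* > 0")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def multinomial_covariance(p: ProbabilityVector) -> np.ndarray:
    """Covariance of sqrt(n)(p_hat - p): ``D_p - p p'``.

    Rows sum to zero (the proportions sum to one) and the matrix is positive
    semidefinite of rank at most k - 1.
    """
    v = p.values
    return np.diag(v) - np.outer(v, v)


def _require_positive(p: np.ndarray, what: str) -> None:
    if np.any(p <= 0):
        raise DegenerateSupportError(
            f"{what} diverges at zero probabilities; all p_l must be positive "
            "(or enable the zero floor in asymptotic_law)"
        )


def entropy_gradient(p: ProbabilityVector, spec: EntropySpec) -> np.ndarray:
    """Matrix B of partial derivatives of the per-category functions h_l.

    For Shannon/Tsallis/Renyi the h_l depend on p_l only, so B is diagonal
    (k x k); for Fisher each h_l = (sqrt p_{l+1} - sqrt p_l)^2 involves two
    neighbouring categories, so B is (k-1) x k with two non-zeros per row.
    """
    v = p.values
    k = p.k
    if spec.family == "shannon":
        _require_positive(v, "the Shannon gradient log(p) + 1")
        return np.diag(np.log(v) + 1.0)
    if spec.family == "tsallis":
        if spec.q < 1:
            _require_positive(v, f"the Tsallis gradient with q={spec.q} < 1")
        return np.diag(1.0 - spec.q * v ** (spec.q - 1.0))
    if spec.family == "renyi":
        if spec.q < 1:
            _require_positive(v, f"the Renyi gradient with q={spec.q} < 1")
        return np.diag(spec.q * v ** (spec.q - 1.0))
    # fisher: rows l = 1..k-1, non-zeros at columns l and l+1
    _require_positive(v, "the Fisher gradient 1/sqrt(p)")
    s = np.sqrt(v)
    d = s[1:] - s[:-1]
    B = np.zeros((k - 1, k))
    idx = np.arange(k - 1)
    B[idx, idx] = -d / s[:-1]
    B[idx, idx + 1] = d / s[1:]
    return B


def delta_covariance(p: ProbabilityVector, spec: EntropySpec) -> np.ndarray:
    """Covariance ``B Sigma_p B'`` of the delta-method multivariate limit."""
    B = entropy_gradient(p, spec)
    return B @ multinomial_covariance(p) @ B.T


def closed_form_delta_covariance(p: ProbabilityVector, spec: EntropySpec) -> np.ndarray:
    """Entry-wise closed forms of the delta covariance for the diagonal-gradient
    families (Shannon, Tsallis, Renyi).  Used as an independent cross-check of
    :func:`delta_covariance`.
    """
    v = p.values
    q = spec.q
    if spec.family == "shannon":
        a = np.log(v) + 1.0
        diag = (v - v**2) * a**2
        off = -np.outer(v * a, v * a)
    elif spec.family == "tsallis":
        a = 1.0 - q * v ** (q - 1.0)
        diag = (v - v**2) * a**2
        off = -np.outer(v * a, v * a)
    elif spec.family == "renyi":
        diag = q**2 * (v - v**2) * v ** (2.0 * (q - 1.0))
        off = -(q**2) * np.outer(v, v) ** q
    else:
        raise InvalidInputError("closed forms are given for shannon/tsallis/renyi only")
    out = off
    np.fill_diagonal(out, diag)
    return out


def fisher_paper_sigma_star(p: ProbabilityVector) -> float:
    """The published closed-form Sigma* for the Fisher information variance,
    transcribed verbatim — including its asymmetric last diagonal term — and
    retained only for comparison with the delta-method variance.
    """
    v = p.values
    s = np.sqrt(v)
    k = p.k
    d = s[1:] - s[:-1]  # d[l] = sqrt(p_{l+2}) - sqrt(p_{l+1}) 0-based: l=0..k-2
    total = d[k - 2] ** 2 * (1.0 - v[k - 2])
    # diagonal terms l = 1..k-2 (1-based)
    for ell in range(k - 2):
        total += d[ell] ** 2 * (
            2.0 * s[ell] * s[ell + 1] - v[ell] - v[ell + 1] + 2.0
        )
    # well-separated pairs
    for ell in range(2, k - 2):
        for j in range(ell - 1):
            total += 2.0 * d[ell] * d[j] * (
                s[ell + 1] * s[j] + s[ell] * s[j + 1]
                - s[ell] * s[j] - s[ell + 1] * s[j + 1]
            )
    # last row against the interior
    for j in range(k - 2):
        total += 2.0 * d[k - 2] * d[j] * (s[k - 1] * s[j + 1] - s[k - 2] * s[j])
    # adjacent pairs
    for ell in range(1, k - 2):
        total += 2.0 * d[ell] * d[ell - 1] * (
            s[ell + 1] * s[ell - 1] - s[ell] * s[ell - 1]
            - s[ell + 1] * s[ell] + v[ell] - 1.0
        )
    return float(total)


def _masked(
    v: np.ndarray, floor: float | None, what: str
) -> np.ndarray:
    """Drop categories below the zero floor from divergent variance sums."""
    if floor is None:
        _require_positive(v, what)
        return v
    mask = v >= floor
    if not np.all(mask):
        warnings.warn(
            f"{what}: {int((~mask).sum())} categor(ies) below the zero floor "
            f"{floor:g} excluded from the variance sums",
            RuntimeWarning,
            stacklevel=3,
        )
    return v[mask]


def _contraction_variance(v: np.ndarray, a_v: np.ndarray, a_sq_v: np.ndarray) -> float:
    """Variance of a' Z for Z ~ N(., Sigma_p): sum p a^2 - (sum p a)^2,
    supplied as the already p-weighted terms ``a_v = p*a`` and
    ``a_sq_v = p*a^2`` so zero-cell limits can be taken upstream."""
    return float(a_sq_v.sum() - a_v.sum() ** 2)


def _shannon_variance(v: np.ndarray, n: int) -> float:
    pos = v > 0
    vp = v[pos]
    a = np.log(vp) + 1.0
    return _contraction_variance(vp, vp * a, vp * a**2) / n


def _tsallis_variance(v: np.ndarray, n: int, q: float, floor: float | None) -> float:
    if 2.0 * q - 1.0 < 0:
        v = _masked(v, floor, f"Tsallis variance with q={q} < 1/2")
    pos = v > 0
    vp = v[pos]
    # p*a = (p - q p^q)/(q-1);  p*a^2 = (p - 2q p^q + q^2 p^{2q-1})/(q-1)^2
    pa = (vp - q * vp**q) / (q - 1.0)
    pa2 = (vp - 2.0 * q * vp**q + q**2 * vp ** (2.0 * q - 1.0)) / (q - 1.0) ** 2
    return _contraction_variance(vp, pa, pa2) / n


def _power_sum_variance(v: np.ndarray, n: int, q: float, floor: float | None) -> float:
    """sigma*^2 of S = sum p_hat^q: (q^2/n)[sum p^{2q-1} - (sum p^q)^2]."""
    if 2.0 * q - 1.0 < 0:
        v = _masked(v, floor, f"Renyi power-sum variance with q={q} < 1/2")
    vp = v[v > 0]
    return q**2 * float((vp ** (2.0 * q - 1.0)).sum() - (vp**q).sum() ** 2) / n


def _fisher_variance(v: np.ndarray, n: int, f0: float) -> float:
    """Delta-method variance g' Sigma_p g / n via the p-weighted contraction.

    With g_j the scalar gradient of the Fisher functional, both p_j g_j and
    p_j g_j^2 have finite limits as p_j -> 0, so zero cells need no floor.
    """
    s = np.sqrt(v)
    c = np.empty_like(s)  # c_j = sqrt(p_j) * g_j / F0
    c[0] = s[0] - s[1]
    c[-1] = s[-1] - s[-2]
    if v.size > 2:
        c[1:-1] = 2.0 * s[1:-1] - s[:-2] - s[2:]
    return f0**2 * _contraction_variance(v, c * s, c**2) / n


def asymptotic_law(
    p: ProbabilityVector,
    n: int,
    spec: EntropySpec,
    zero_floor: float | None = ZERO_FLOOR_DEFAULT,
) -> AsymptoticLaw:
    """Closed-form limit law of the plug-in entropy of a Mult(n, p) sample.

    ``zero_floor`` controls divergent zero-cell variance terms: categories with
    ``p_l`` below the floor are excluded (with a warning); pass ``None`` to
    raise instead.  Variance scales exactly as 1/n.
    """
    if n < 1:
        raise InvalidInputError("sample size n must be >= 1")
    v = p.values
    k = p.k
    point_mass = bool(np.max(v) >= 1.0 - 1e-15)

    if spec.family == "shannon":
        mean = entropy(p, spec)
        var = _shannon_variance(v, n)
        if spec.normalized:
            var /= np.log(k) ** 2
        return AsymptoticLaw(
            "shannon", "normal", mean, var, n, k,
            normalized=spec.normalized, degenerate=point_mass,
        )

    if spec.family == "tsallis":
        mean = entropy(p, spec)
        var = _tsallis_variance(v, n, spec.q, zero_floor)
        if spec.normalized:
            var *= tsallis_normalization(k, spec.q) ** 2
        return AsymptoticLaw(
            "tsallis", "normal", mean, var, n, k,
            normalized=spec.normalized, q=spec.q, degenerate=point_mass,
        )

    if spec.family == "fisher":
        mean = entropy(p, spec)
        if spec.fisher_variance_mode == "paper":
            _require_positive(v, "the published Fisher variance form")
            var = spec.fisher_constant * fisher_paper_sigma_star(p) / n
            var = max(var, 0.0)
        else:
            var = _fisher_variance(v, n, spec.fisher_constant)
        return AsymptoticLaw(
            "fisher", "normal", mean, var, n, k, degenerate=point_mass,
        )

    # renyi
    q = spec.q
    mu_star = float((v[v > 0] ** q).sum())
    sigma_star_sq = _power_sum_variance(v, n, q, zero_floor)
    mean = renyi(p, q, normalized=spec.normalized)
    if point_mass or sigma_star_sq <= 0.0:
        return AsymptoticLaw(
            "renyi", "log_power_normal", mean, 0.0, n, k,
            normalized=spec.normalized, q=q,
            power_sum_mean=mu_star, power_sum_sd=0.0, degenerate=True,
        )
    if spec.renyi_variance_convention == "power_sum":
        var = sigma_star_sq
    else:
        var = sigma_star_sq / ((1.0 - q) ** 2 * mu_star**2)
        if spec.normalized:
            var /= np.log(k) ** 2
    return AsymptoticLaw(
        "renyi", "log_power_normal", mean, var, n, k,
        normalized=spec.normalized, q=q,
        power_sum_mean=mu_star, power_sum_sd=float(np.sqrt(sigma_star_sq)),
    )


def _renyi_scale(law: AsymptoticLaw) -> float:
    """Scale factor mapping the raw Renyi variate onto the reported one."""
    return float(np.log(law.k)) if law.normalized else 1.0


def renyi_limit_density(x, law: AsymptoticLaw):
    """Density of the Renyi limit law H = log|S| / (1 - q), S ~ N(mu*, sigma*^2).

    Change of variables gives, with s(x) = exp((1-q) x),

        f(x) = |1-q| s(x) [phi((s-mu*)/sigma*) + phi((s+mu*)/sigma*)] / sigma*

    (the second kernel is the |S| reflection; it is negligible when
    mu*/sigma* is large but keeps the density an exact probability density).
    For a normalized law the density of H/log(k) is log(k) f(x log k).
    """
    if law.shape != "log_power_normal":
        raise InvalidInputError("renyi_limit_density requires a log-power-normal law")
    if law.degenerate:
        raise InvalidInputError("degenerate (zero-variance) Renyi law has no density")
    scale = _renyi_scale(law)
    x = np.asarray(x, dtype=float) * scale
    q, mu, sd = law.q, law.power_sum_mean, law.power_sum_sd
    s = np.exp((1.0 - q) * x)
    f = (
        abs(1.0 - q)
        * s
        * (stats.norm.pdf((s - mu) / sd) + stats.norm.pdf((s + mu) / sd))
        / sd
    )
    return f * scale


def renyi_limit_cdf(x, law: AsymptoticLaw):
    """CDF of the Renyi limit law (see :func:`renyi_limit_density`)."""
    if law.shape != "log_power_normal":
        raise InvalidInputError("renyi_limit_cdf requires a log-power-normal law")
    scale = _renyi_scale(law)
    x = np.asarray(x, dtype=float) * scale
    q, mu, sd = law.q, law.power_sum_mean, law.power_sum_sd
    s = np.exp((1.0 - q) * x)
    inner = stats.norm.cdf((s - mu) / sd) - stats.norm.cdf((-s - mu) / sd)
    if q < 1.0:  # H increasing in |S|
        return inner
    return 1.0 - inner


def law_sampler(
    law: AsymptoticLaw, size: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw from an asymptotic law (for goodness-of-fit and visualisation).

    Normal laws yield Gaussian draws; the Renyi law transforms Gaussian
    power-sum draws through H = log|S|/(1-q) (scaled by 1/log k if
    normalized).  Reproducible for a fixed integer seed.
    """
    if size < 1:
        raise InvalidInputError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if law.degenerate or law.variance == 0.0:
        warnings.warn("sampling from a degenerate law returns constants", RuntimeWarning)
        return np.full(size, law.mean)
    if law.shape == "normal":
        return rng.normal(law.mean, law.sd, size=size)
    s = rng.normal(law.power_sum_mean, law.power_sum_sd, size=size)
    h = np.log(np.abs(s)) / (1.0 - law.q)
    return h / _renyi_scale(law)
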