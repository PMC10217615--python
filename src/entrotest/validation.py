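"""Simulation validation of the asymptotic laws.

Three pieces of machinery:

* ``normality_sweep`` — for each design cell, draw replicate multinomial
  samples, compute the plug-in entropy of each, and run an Anderson–Darling
  test of normality on the replicate values.
* ``gof_sweep`` — same replicates, but a one-sample Kolmogorov–Smirnov test
  of the replicate entropies against the closed-form asymptotic law evaluated
  at the *true* generating probabilities.
* ``variance_calibration`` — Monte-Carlo check that empirical means and
  variances of replicate entropies match the asymptotic law.

The default grid covers three probability profiles (Linear, One-Almost-Zero,
Half-and-Half with eps in {0.1, 0.3, 0.5, 0.8}), k in {6, 24, 120, 720},
sample sizes n = m*k for m in {100, 1000, 10000}, and six entropy functionals
(Shannon, Tsallis 1/2 and 3/2, Renyi 1/3 and 2/3, Fisher) — 432 cells.

Replicates are drawn once per (model, k, n) cell and shared across the six
functionals; per-cell seeds are derived deterministically from the master
seed and the cell coordinates, so results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .asymptotics import asymptotic_law, renyi_limit_cdf
from .counts import (
    EPS0_DEFAULT,
    ProbabilityVector,
    half_and_half_model,
    linear_model,
    one_almost_zero_model,
)
from .estimators import EntropySpec
from .exceptions import InvalidInputError

__all__ = [
    "SimulationDesign",
    "SweepResult",
    "reference_design",
    "default_specs",
    "normality_sweep",
    "gof_sweep",
    "variance_calibration",
    "CalibrationReport",
]


def default_specs() -> tuple[EntropySpec, ...]:
    """The six functionals of the reference grid (raw scale; normality and
    goodness of fit are unaffected by the affine normalization)."""
    return (
        EntropySpec("shannon"),
        EntropySpec("tsallis", q=0.5),
        EntropySpec("tsallis", q=1.5),
        EntropySpec("renyi", q=1.0 / 3.0),
        EntropySpec("renyi", q=2.0 / 3.0),
        EntropySpec("fisher"),
    )


@dataclass(frozen=True)
class SimulationDesign:
    """A full sweep design: cells are the cross product of models x k x n x specs.

    ``models`` is a list of ``(name, param)`` pairs where name is one of
    ``linear`` (param ignored), ``oaz`` (param = eps0) and ``hah``
    (param = eps).  ``n_multipliers`` m give sample sizes n = m * k.
    """

    models: tuple = (
        ("linear", 0.0),
        ("oaz", EPS0_DEFAULT),
        ("hah", 0.1),
        ("hah", 0.3),
        ("hah", 0.5),
        ("hah", 0.8),
    )
    k_values: tuple = (6, 24, 120, 720)
    n_multipliers: tuple = (100, 1000, 10000)
    specs: tuple = field(default_factory=default_specs)
    replicates: int = 300
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise InvalidInputError("at least 2 replicates are required")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("alpha must lie in (0, 1)")

    def probability(self, model: str, param: float, k: int) -> ProbabilityVector:
        if model == "linear":
            return linear_model(k)
        if model == "oaz":
            return one_almost_zero_model(k, eps0=param)
        if model == "hah":
            return half_and_half_model(k, eps=param)
        raise InvalidInputError(f"unknown model {model!r}")


@dataclass(frozen=True)
class SweepResult:
    """One row per (spec, model, k, n) cell plus rejection summary."""

    table: pd.DataFrame
    alpha: float

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def n_rejections(self) -> int:
        return int((self.table["reject"] & ~self.table["degenerate"]).sum())

    def summary(self) -> str:
        return (
            f"{self.n_rejections} of {self.n_cells} cells reject "
            f"at level {self.alpha:g}"
        )


def _cell_rng(seed: int, *coords: int) -> np.random.Generator:
    """Deterministic per-cell generator, independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence([seed, *coords]))


def _replicate_entropies(
    p: ProbabilityVector, n: int, reps: int, rng: np.random.Generator,
    specs: tuple,
) -> dict[int, np.ndarray]:
    """Draw reps multinomial samples once and evaluate every spec on them."""
    x = rng.multinomial(n, p.values, size=reps)
    ph = x / n
    return {i: _entropy_of_proportions(ph, spec) for i, spec in enumerate(specs)}


def _sweep(design: SimulationDesign, mode: str) -> SweepResult:
    rows = []
    for im, (model, param) in enumerate(design.models):
        for ik, k in enumerate(design.k_values):
            p = design.probability(model, param, k)
            for imult, mult in enumerate(design.n_multipliers):
                n = mult * k
                rng = _cell_rng(design.seed, im, ik, imult)
                entropies = _replicate_entropies(
                    p, n, design.replicates, rng, design.specs
                )
                for ispec, spec in enumerate(design.specs):
                    h = entropies[ispec]
                    degenerate = bool(np.ptp(h) == 0.0 or not np.all(np.isfinite(h)))
                    if degenerate:
                        pval = np.nan
                    elif mode == "ad":
                        pval = float(normal_ad(h)[1])
                    else:
                        pval = _ks_pvalue(h, p, n, spec)
                        degenerate = bool(np.isnan(pval))
                    rows.append(
                        {
                            "family": spec.label,
                            "q": spec.q if spec.q is not None else np.nan,
                            "model": model,
                            "eps": param,
                            "k": k,
                            "n": n,
                            "p_value": pval,
                            "reject": bool(pval < design.alpha)
                            if np.isfinite(pval)
                            else False,
                            "degenerate": degenerate,
                        }
                    )
    return SweepResult(table=pd.DataFrame(rows), alpha=design.alpha)


def _ks_pvalue(h: np.ndarray, p: ProbabilityVector, n: int, spec: EntropySpec) -> float:
    """One-sample KS p-value of replicate entropies against the asymptotic law
    evaluated at the true generating probabilities."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        law = asymptotic_law(p, n, spec)
    if law.variance == 0.0 and law.shape == "normal":
        return np.nan
    if law.shape == "normal":
        cdf = stats.norm(loc=law.mean, scale=law.sd).cdf
    else:
        if law.degenerate:
            return np.nan
        cdf = lambda x: renyi_limit_cdf(x, law)  # noqa: E731
    return float(stats.kstest(h, cdf).pvalue)


def normality_sweep(design: SimulationDesign) -> SweepResult:
    """Anderson–Darling normality sweep over the design grid.

    For each cell, draws ``design.replicates`` samples, computes the plug-in
    entropy of each, and records the AD p-value of the normality hypothesis.
    Degenerate cells (constant replicate values) are flagged, not rejected.
    """
    return _sweep(design, "ad")


def gof_sweep(design: SimulationDesign) -> SweepResult:
    """Kolmogorov–Smirnov goodness-of-fit sweep against the asymptotic laws.

    Normal-limit families are tested against their normal law; Renyi is
    tested against its log-power-normal law.  Reference laws are evaluated at
    the true model probabilities with the default zero floor.
    """
    return _sweep(design, "ks")


def reference_design(
    seed: int,
    replicates: int = 300,
    alpha: float = 0.01,
) -> SimulationDesign:
    """The reference 432-cell grid (6 specs x 6 model configs x 4 k x 3 n)."""
    return SimulationDesign(seed=seed, replicates=replicates, alpha=alpha)


def ks_design(seed: int, replicates: int = 50, alpha: float = 0.05) -> SimulationDesign:
    """The goodness-of-fit variant of the reference grid (50 replicates, 5%)."""
    return SimulationDesign(seed=seed, replicates=replicates, alpha=alpha)


@dataclass(frozen=True)
class CalibrationReport:
    """Monte-Carlo vs asymptotic moments for one (p, n, spec) setting."""

    empirical_mean: float
    empirical_variance: float
    asymptotic_mean: float
    asymptotic_variance: float
    replicates: int

    @property
    def mean_ratio(self) -> float:
        return self.empirical_mean / self.asymptotic_mean

    @property
    def variance_ratio(self) -> float:
        return self.empirical_variance / self.asymptotic_variance


def variance_calibration(
    p: ProbabilityVector,
    n: int,
    spec: EntropySpec,
    replicates: int,
    seed: int,
) -> CalibrationReport:
    """Compare empirical replicate moments with the asymptotic law.

    For Renyi the calibrated quantity is the power sum ``S = sum p_hat^q``
    (whose law is normal with parameters mu*, sigma*^2); for the other
    families it is the plug-in entropy itself.
    """
    if replicates < 100:
        raise InvalidInputError("variance calibration needs at least 100 replicates")
    rng = np.random.default_rng(seed)
    x = rng.multinomial(n, p.values, size=replicates)
    ph = x / n
    law = asymptotic_law(p, n, spec)
    if spec.family == "renyi":
        vals = np.where(ph > 0, ph**spec.q, 0.0).sum(axis=1)
        a_mean, a_var = law.power_sum_mean, law.power_sum_sd**2
    else:
        vals = _entropy_of_proportions(ph, spec)
        a_mean, a_var = law.mean, law.variance
    return CalibrationReport(
        empirical_mean=float(vals.mean()),
        empirical_variance=float(vals.var(ddof=1)),
        asymptotic_mean=a_mean,
        asymptotic_variance=a_var,
        replicates=replicates,
    )


def _entropy_of_proportions(ph: np.ndarray, spec: EntropySpec) -> np.ndarray:
    """Vectorized plug-in entropy over rows of a proportions matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if spec.family == "shannon":
            h = -np.where(ph > 0, ph * np.log(np.where(ph > 0, ph, 1.0)), 0.0).sum(axis=1)
            if spec.normalized:
                h = h / np.log(ph.shape[1])
        elif spec.family == "tsallis":
            h = (ph - np.where(ph > 0, ph**spec.q, 0.0)).sum(axis=1) / (spec.q - 1)
            if spec.normalized:
                from .estimators import tsallis_normalization

                h = h * tsallis_normalization(ph.shape[1], spec.q)
        elif spec.family == "renyi":
            s = np.where(ph > 0, ph**spec.q, 0.0).sum(axis=1)
            h = np.log(s) / (1.0 - spec.q)
            if spec.normalized:
                h = h / np.log(ph.shape[1])
        else:
            sq = np.sqrt(ph)
            h = spec.fisher_constant * ((sq[:, 1:] - sq[:, :-1]) ** 2).sum(axis=1)
    return np.asarray(h, dtype=float)
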