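"""Two-sample entropy tests and the chi-square homogeneity baseline.

The entropy test compares one scalar functional per sample:

    z = |H1(p1_hat) - H2(p2_hat)| / sqrt(var1 + var2),    p = 2(1 - Phi(z)),

with each variance taken from the sample's own asymptotic law at its plug-in
proportions and its own n.  Because normalized entropies live on [0, 1]
regardless of the number of categories, the two samples may have different k
— and even different entropy families, in which case the null is equality of
the two (different) functionals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .asymptotics import asymptotic_law
from .counts import CountTable
from .estimators import EntropySpec
from .exceptions import DegenerateTestError, InvalidInputError

__all__ = [
    "TestResult",
    "entropy_two_sample_test",
    "two_sample_test_from_results",
    "chi_square_homogeneity",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of the two-sample entropy z-test."""

    z_statistic: float
    p_value: float
    estimate1: float
    estimate2: float
    variance1: float
    variance2: float
    spec1: EntropySpec
    spec2: EntropySpec
    n1: int
    n2: int
    k1: int
    k2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "z_statistic": self.z_statistic,
            "p_value": self.p_value,
            "estimate1": self.estimate1,
            "estimate2": self.estimate2,
            "variance1": self.variance1,
            "variance2": self.variance2,
            "family1": self.spec1.label,
            "family2": self.spec2.label,
            "n1": self.n1,
            "n2": self.n2,
            "k1": self.k1,
            "k2": self.k2,
        }


def _z_test(h1, v1, h2, v2) -> tuple[float, float]:
    if v1 + v2 <= 0.0:
        raise DegenerateTestError(
            "both asymptotic variances are zero; the z statistic is undefined"
        )
    z = abs(h1 - h2) / np.sqrt(v1 + v2)
    return float(z), float(2.0 * stats.norm.sf(z))


def entropy_two_sample_test(
    counts1: CountTable,
    counts2: CountTable,
    spec1: EntropySpec,
    spec2: EntropySpec | None = None,
    zero_floor: float | None = 1e-10,
) -> TestResult:
    """Two-sided z-test of equal entropy between two multinomial samples.

    ``spec2`` defaults to ``spec1``.  For Renyi, the default power-sum
    variance convention uses sigma*^2 of the power sum as the per-sample
    variance.  Raw (unnormalized) entropies of samples with different k are
    on different scales; use ``normalized=True`` specs to compare across k.
    """
    if spec2 is None:
        spec2 = spec1
    elif (spec2.family, spec2.q) != (spec1.family, spec1.q):
        warnings.warn(
            "comparing different entropy functionals: the null hypothesis is "
            "equality of the two different quantities, not of the distributions",
            UserWarning,
        )
    law1 = asymptotic_law(counts1.proportions(), counts1.n, spec1, zero_floor)
    law2 = asymptotic_law(counts2.proportions(), counts2.n, spec2, zero_floor)
    z, p = _z_test(law1.mean, law1.variance, law2.mean, law2.variance)
    return TestResult(
        z_statistic=z, p_value=p,
        estimate1=law1.mean, estimate2=law2.mean,
        variance1=law1.variance, variance2=law2.variance,
        spec1=spec1, spec2=spec2,
        n1=counts1.n, n2=counts2.n, k1=counts1.k, k2=counts2.k,
    )


def two_sample_test_from_results(res1, res2) -> TestResult:
    """Entropy z-test from two fitted :class:`~entrotest.model.EntropyResults`."""
    l1, l2 = res1.law, res2.law
    z, p = _z_test(l1.mean, l1.variance, l2.mean, l2.variance)
    return TestResult(
        z_statistic=z, p_value=p,
        estimate1=l1.mean, estimate2=l2.mean,
        variance1=l1.variance, variance2=l2.variance,
        spec1=res1.model.spec, spec2=res2.model.spec,
        n1=l1.n, n2=l2.n, k1=l1.k, k2=l2.k,
    )


def chi_square_homogeneity(
    counts1: CountTable, counts2: CountTable
) -> tuple[float, float]:
    """Pearson chi-square homogeneity test on the stacked 2 x k table.

    Returns ``(statistic, p_value)`` with k - 1 degrees of freedom.  The two
    samples must share the same categories; the entropy test above is the
    alternative when they do not.
    """
    if counts1.k != counts2.k:
        raise InvalidInputError(
            "chi-square homogeneity requires the same number of categories"
        )
    table = np.vstack([counts1.counts, counts2.counts])
    if np.any(table.sum(axis=0) == 0):
        raise InvalidInputError("every pooled category total must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
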