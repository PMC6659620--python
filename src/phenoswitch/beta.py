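"""Beta-distribution characterization of the tolerant-fraction distribution.

The across-sample distribution of the tolerant fraction lives on [0, 1], so
its natural two-parameter summary is a Beta density matched to the measured
mean and variance.  Moment matching is the canonical fit here; maximum
likelihood is available as a cross-check but can diverge when fractions sit
exactly on the boundary (the log-likelihood is unbounded for exponents < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import betaln

from phenoswitch.errors import DomainError
from phenoswitch.simulate import FractionDistribution

__all__ = [
    "BetaParameters",
    "beta_from_moments",
    "beta_pdf",
    "fit_empirical_fractions",
    "BetaFitReport",
]


@dataclass(frozen=True)
class BetaParameters:
    """The two positive exponents of a Beta density on [0, 1]."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise DomainError(f"Beta exponents must be positive, got ({self.a}, {self.b})")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def frozen(self):
        """The scipy frozen distribution with these exponents."""
        return stats.beta(self.a, self.b)


def beta_from_moments(mean: float, variance: float) -> BetaParameters:
    """Moment-matched Beta exponents for a given mean and variance.

    ``a = mean * (mean (1 - mean) - variance) / variance`` and
    ``b = a (1 - mean) / mean``.  Feasibility requires
    ``0 < variance < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise DomainError(f"mean={mean} must lie strictly inside (0, 1)")
    if not 0.0 < variance < mean * (1.0 - mean):
        raise DomainError(
            f"variance={variance} infeasible: must lie in (0, {mean * (1 - mean)})"
        )
    a = mean * (mean * (1.0 - mean) - variance) / variance
    b = a * (1.0 - mean) / mean
    return BetaParameters(a=a, b=b)


def beta_pdf(p, params: BetaParameters):
    """Beta density evaluated in log space; vectorized over ``p``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("fractions must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logpdf = (
            (params.a - 1.0) * np.log(p)
            + (params.b - 1.0) * np.log1p(-p)
            - betaln(params.a, params.b)
        )
    out = np.exp(logpdf)
    return out if out.ndim else float(out)


@dataclass
class BetaFitReport:
    """Moment-matched Beta fit of an empirical fraction sample."""

    params: BetaParameters | None
    mean: float
    variance: float
    ks_distance: float | None
    n: int
    n_extinct: int
    degenerate: bool = False
    mle_params: BetaParameters | None = None

    def to_dict(self) -> dict:
        return {
            "a": None if self.params is None else self.params.a,
            "b": None if self.params is None else self.params.b,
            "mean": self.mean,
            "variance": self.variance,
            "ks_distance": self.ks_distance,
            "n": self.n,
            "n_extinct": self.n_extinct,
            "degenerate": self.degenerate,
        }


def fit_empirical_fractions(
    dist: FractionDistribution,
    *,
    min_n: int = 100,
    with_mle: bool = False,
) -> BetaFitReport:
    """Moment-matched Beta fit of an empirical fraction distribution.

    The exponents come from the sample mean and (unbiased) variance; the
    Kolmogorov-Smirnov distance between the empirical CDF and the fitted
    continuous Beta CDF is reported as the goodness-of-fit diagnostic.
    Fractions exactly 0 or 1 are retained in the moments.  An infeasible
    moment pair (all mass on a boundary, or variance at the Bernoulli limit)
    yields a degenerate report instead of a fit.
    """
    frac = np.asarray(dist.fractions, dtype=float)
    if frac.size < min_n:
        raise DomainError(
            f"need >= {min_n} surviving fractions for a stable fit, got {frac.size}"
        )
    mean = float(np.mean(frac))
    variance = float(np.var(frac, ddof=1))
    if not (0.0 < mean < 1.0) or not (0.0 < variance < mean * (1.0 - mean)):
        return BetaFitReport(
            params=None, mean=mean, variance=variance, ks_distance=None,
            n=frac.size, n_extinct=dist.n_extinct, degenerate=True,
        )
    params = beta_from_moments(mean, variance)
    ks = float(stats.kstest(frac, params.frozen().cdf).statistic)
    mle = None
    if with_mle:
        interior = frac[(frac > 0) & (frac < 1)]
        if interior.size >= min_n:
            a_mle, b_mle, _, _ = stats.beta.fit(interior, floc=0.0, fscale=1.0)
            mle = BetaParameters(a=float(a_mle), b=float(b_mle))
    return BetaFitReport(
        params=params, mean=mean, variance=variance, ks_distance=ks,
        n=frac.size, n_extinct=dist.n_extinct, mle_params=mle,
    )
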