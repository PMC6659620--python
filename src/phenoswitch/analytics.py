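"""Closed-form moments and generating functions for both model phases.

Drug phase (births suppressed, ``k_E = k_M = 0``): each cell evolves
independently under the 2x2 single-cell rate matrix

    A = [[-(k_EM + mu_E), k_ME],
         [k_EM, -(k_ME + mu_M)]],

whose eigenvalues are ``-(gamma0 +/- alpha0)/2``.  All drug-phase results are
expressed through ``exp(A t)``, written in the numerically stable form

    exp(A t) = exp(-gamma0 t / 2) * [cosh(x) I + t * sinch(x) * S],

with ``x = alpha0 t / 2``, ``S = A + (gamma0/2) I`` (so ``S^2 = (alpha0/2)^2 I``)
and ``sinch(x) = sinh(x)/x``.  The ``sinch`` form evaluates the degenerate
``alpha0 -> 0`` limit exactly instead of dividing 0/0.

Growth phase: the first moments obey the mean-field matrix
``B = [[kEf - k_EM, k_ME], [k_EM, kMf - k_ME]]``; second moments close into a
linear 5-dimensional system solved by matrix exponentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.linalg import expm

from phenoswitch.errors import DomainError, NumericalError
from phenoswitch.model import (
    GrowthPhaseRates,
    InitialComposition,
    RateParameters,
    drug_phase_rates,
    growth_phase_rates,
)

__all__ = [
    "SingleCellOccupancy",
    "MomentSummary",
    "drug_matrix",
    "growth_matrix",
    "moment_matrix",
    "single_cell_occupancy",
    "single_cell_gf",
    "population_gf",
    "mean_surviving_drug",
    "fano_drug",
    "script_F_theory",
    "script_F_empirical",
    "mean_growth",
    "moments_growth",
]


def _sinch(x):
    """sinh(x)/x with the exact value 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = np.sinh(x[nz]) / x[nz]
    return out if out.ndim else float(out)


def _exp_cosh(u, x):
    """exp(u) * cosh(x) without overflowing when u + x stays bounded."""
    return 0.5 * (np.exp(u + x) + np.exp(u - x))


def _exp_sinch(u, x):
    """exp(u) * sinh(x)/x, overflow-safe for large x and exact at x = 0."""
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    small = x < 30.0
    out = np.empty(np.broadcast(u, x).shape)
    u_b, x_b = np.broadcast_arrays(u, x)
    # direct sinh is accurate (no cancellation) and cannot overflow below 30
    out[small] = np.exp(u_b[small]) * _sinch(x_b[small])
    big = ~small
    out[big] = (np.exp(u_b[big] + x_b[big]) - np.exp(u_b[big] - x_b[big])) / (
        2.0 * x_b[big]
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SingleCellOccupancy:
    """Type-occupancy probabilities of a single drug-phase cell."""

    P_E: float
    P_M: float

    @property
    def P_dead(self) -> float:
        return 1.0 - self.P_E - self.P_M

    @property
    def P_alive(self) -> float:
        return self.P_E + self.P_M


@dataclass
class MomentSummary:
    """First and second moments of (E, M, N) on a time grid.

    ``var_N`` is always assembled as ``var_E + var_M + 2*cov_EM`` so the
    variance decomposition holds exactly.  ``fano_N`` is NaN where
    ``mean_N`` is zero.  Raw second moments are kept alongside the central
    ones.
    """

    t: np.ndarray
    mean_E: np.ndarray
    mean_M: np.ndarray
    var_E: np.ndarray
    var_M: np.ndarray
    cov_EM: np.ndarray
    EE: np.ndarray = None  # <E^2>
    MM: np.ndarray = None  # <M^2>
    EM: np.ndarray = None  # <EM>
    fano_se: np.ndarray = None  # bootstrap SE of fano_N, when available
    mean_N: np.ndarray = field(init=False)
    var_N: np.ndarray = field(init=False)
    fano_N: np.ndarray = field(init=False)

    def __post_init__(self):
        for name in ("t", "mean_E", "mean_M", "var_E", "var_M", "cov_EM"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if self.EE is None:
            self.EE = self.var_E + self.mean_E**2
        if self.MM is None:
            self.MM = self.var_M + self.mean_M**2
        if self.EM is None:
            self.EM = self.cov_EM + self.mean_E * self.mean_M
        self.mean_N = self.mean_E + self.mean_M
        self.var_N = self.var_E + self.var_M + 2.0 * self.cov_EM
        with np.errstate(divide="ignore", invalid="ignore"):
            self.fano_N = np.where(self.mean_N > 0, self.var_N / self.mean_N, np.nan)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t": self.t,
            "mean_E": self.mean_E, "mean_M": self.mean_M, "mean_N": self.mean_N,
            "var_E": self.var_E, "var_M": self.var_M,
            "cov_EM": self.cov_EM, "var_N": self.var_N,
            "fano_N": self.fano_N,
        }
        if self.fano_se is not None:
            cols["fano_se"] = self.fano_se
        return pd.DataFrame(cols)


def drug_matrix(params: RateParameters) -> np.ndarray:
    """Single-cell rate matrix of the drug phase acting on (P_E, P_M)."""
    return np.array(
        [
            [-(params.k_EM + params.mu_E), params.k_ME],
            [params.k_EM, -(params.k_ME + params.mu_M)],
        ]
    )


def growth_matrix(params: RateParameters) -> np.ndarray:
    """Mean-field matrix of the growth phase acting on (<E>, <M>)."""
    kEf = params.k_E - params.mu_E
    kMf = params.k_M - params.mu_M
    return np.array(
        [
            [kEf - params.k_EM, params.k_ME],
            [params.k_EM, kMf - params.k_ME],
        ]
    )


def _drug_propagator(params: RateParameters, t):
    """exp(A t) for the drug-phase matrix, vectorized over t, alpha0-safe."""
    comp = drug_phase_rates(params)
    t = np.asarray(t, dtype=float)
    A = drug_matrix(params)
    S = A + 0.5 * comp.gamma0 * np.eye(2)
    x = 0.5 * comp.alpha0 * t
    u = -0.5 * comp.gamma0 * t
    # shape (..., 2, 2)
    ct = np.asarray(_exp_cosh(u, x))[..., None, None] * np.eye(2)
    st = np.asarray(t * _exp_sinch(u, x))[..., None, None] * S
    return ct + st


def single_cell_occupancy(params: RateParameters, p0: float, t: float) -> SingleCellOccupancy:
    """Probabilities that a drug-phase cell is E-type / M-type at time ``t``.

    The cell starts M-type with probability ``p0``.  Birth rates are ignored
    (drug phase).
    """
    if not 0.0 <= p0 <= 1.0:
        raise DomainError(f"p0={p0} outside [0, 1]")
    if t < 0:
        raise DomainError(f"t={t} must be >= 0")
    P = _drug_propagator(params, float(t)) @ np.array([1.0 - p0, p0])
    return SingleCellOccupancy(P_E=float(P[0]), P_M=float(P[1]))


def single_cell_gf(z1: float, z2: float, params: RateParameters, p0: float, t: float) -> float:
    """Single-cell probability generating function ``g(z1, z2, t | p0)``.

    Equals ``1 - (P_E + P_M) + P_E z1 + P_M z2``: the cell is dead, E-type, or
    M-type.
    """
    occ = single_cell_occupancy(params, p0, t)
    return 1.0 - (occ.P_E + occ.P_M) + occ.P_E * z1 + occ.P_M * z2


def population_gf(
    z1: float,
    z2: float,
    params: RateParameters,
    init: InitialComposition,
    t: float,
    *,
    quad_tol: float = 1e-10,
) -> float:
    """Population generating function ``G(z1, z2, t)`` in the drug phase.

    For a fixed fraction the i.i.d.-cell structure gives ``g^N0`` exactly;
    for a distributed fraction the average over the fraction distribution is
    evaluated by adaptive quadrature (Beta) or as an empirical average.
    """
    kind = init.kind
    if kind == "fixed":
        return single_cell_gf(z1, z2, params, init.p0_mean, t) ** init.N0

    def integrand(p):
        return single_cell_gf(z1, z2, params, p, t) ** init.N0

    if kind == "empirical":
        return float(np.mean([integrand(p) for p in init._empirical]))

    from scipy.stats import beta as beta_dist

    a, b = init._beta
    val, err = integrate.quad(
        lambda p: integrand(p) * beta_dist.pdf(p, a, b),
        0.0, 1.0, epsabs=quad_tol, epsrel=quad_tol, limit=200,
    )
    if err > max(1e-6, 1e-4 * abs(val)):
        raise NumericalError(
            f"quadrature for population_gf did not converge: value={val}, "
            f"error estimate={err}"
        )
    return float(val)


def mean_surviving_drug(params: RateParameters, N0: float, p0: float, t) -> float | np.ndarray:
    """Mean surviving-cell count under drug exposure.

    Bi-exponential closed form; for a distributed initial fraction the mean is
    linear in ``p0``, so pass the mean fraction.  Vectorized over ``t``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise DomainError(f"p0={p0} outside [0, 1]")
    comp = drug_phase_rates(params)
    t = np.asarray(t, dtype=float)
    mu_bar = (1.0 - p0) * params.mu_E + p0 * params.mu_M
    x = 0.5 * comp.alpha0 * t
    u = -0.5 * comp.gamma0 * t
    out = N0 * (
        _exp_cosh(u, x) + (comp.gamma0 - 2.0 * mu_bar) * 0.5 * t * _exp_sinch(u, x)
    )
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _heterogeneity_amplitude(params: RateParameters, t):
    """|difference of the two survival exponentials| / alpha0, alpha0-safe.

    Equals ``(exp(-t(gamma0-alpha0)/2) - exp(-t(gamma0+alpha0)/2)) / alpha0``.
    """
    comp = drug_phase_rates(params)
    t = np.asarray(t, dtype=float)
    return t * _exp_sinch(-0.5 * comp.gamma0 * t, 0.5 * comp.alpha0 * t)


def fano_drug(
    params: RateParameters,
    N0: int,
    p0_mean: float,
    p0_var: float,
    t,
) -> float | np.ndarray:
    """Fano factor of the surviving population under drug exposure.

    ``F = 1 - <N>/N0`` plus a heterogeneity term proportional to the variance
    of the initial tolerant fraction.  Requires the i.i.d.-cell initial
    composition (binomial sampling of types given the fraction).
    """
    if p0_var < 0 or p0_var > p0_mean * (1.0 - p0_mean) + 1e-12:
        raise DomainError(
            f"p0_var={p0_var} infeasible for p0_mean={p0_mean} "
            f"(must lie in [0, {p0_mean * (1 - p0_mean)}])"
        )
    t = np.asarray(t, dtype=float)
    mean_N = mean_surviving_drug(params, N0, p0_mean, t)
    mean_N = np.asarray(mean_N, dtype=float)
    if np.any(mean_N <= 0) or np.any(mean_N < N0 * 1e-300):
        raise NumericalError("mean population is numerically zero; Fano undefined")
    D = (params.mu_E - params.mu_M) * _heterogeneity_amplitude(params, t)
    out = 1.0 - mean_N / N0 + (N0 * (N0 - 1.0) / mean_N) * D**2 * p0_var
    return out if out.ndim else float(out)


def script_F_theory(params: RateParameters, p0_var: float, t) -> float | np.ndarray:
    """Heterogeneity signal: sd of the initial fraction times the decaying
    envelope ``|mu_E - mu_M| / alpha0 * |exp(-t(gamma0-alpha0)/2) -
    exp(-t(gamma0+alpha0)/2)|``.

    Note: the regrouped published form carries growing exponentials
    ``exp(+t(gamma0 -/+ alpha0)/2)``, which is inconsistent with the Fano
    closed form it regroups and diverges in t; this implementation uses the
    decaying sign convention, under which the round trip through
    :func:`script_F_empirical` is an exact identity.
    """
    if p0_var < 0:
        raise DomainError(f"p0_var={p0_var} must be >= 0")
    amp = _heterogeneity_amplitude(params, t)
    out = np.sqrt(p0_var) * abs(params.mu_E - params.mu_M) * np.abs(amp)
    return out if np.ndim(out) else float(out)


def script_F_empirical(F: float, mean_N: float, N0: int) -> float:
    """Heterogeneity signal from measurable quantities.

    ``sqrt((F - 1 + <N>/N0) * <N> / (N0 (N0 - 1)))``.  A negative argument
    signals sub-Poissonian data inconsistent with the heterogeneity model and
    yields NaN with a warning rather than an exception.
    """
    arg = (F - 1.0 + mean_N / N0) * mean_N / (N0 * (N0 - 1.0))
    if arg < 0:
        warnings.warn(
            "negative heterogeneity-signal argument: data are more "
            "sub-Poissonian than the zero-heterogeneity bound; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.sqrt(arg))


def mean_growth(params: RateParameters, E0: float, M0: float, t) -> float | np.ndarray:
    """Mean total population in the growth phase from initial counts (E0, M0)."""
    if E0 < 0 or M0 < 0:
        raise DomainError(f"initial counts must be >= 0, got ({E0}, {M0})")
    comp: GrowthPhaseRates = growth_phase_rates(params)
    t = np.asarray(t, dtype=float)
    x = 0.5 * comp.alphaG * t
    u = -0.5 * comp.gammaG * t
    slope = E0 * (comp.gammaG + 2.0 * comp.kEf) + M0 * (comp.gammaG + 2.0 * comp.kMf)
    out = np.asarray(
        (E0 + M0) * _exp_cosh(u, x) + slope * 0.5 * t * _exp_sinch(u, x)
    )
    return out if out.ndim else float(out)


def moment_matrix(params: RateParameters) -> np.ndarray:
    """Generator of the closed linear system for
    ``(<E>, <M>, <E^2>, <M^2>, <EM>)``."""
    kE, kM = params.k_E, params.k_M
    mE, mM = params.mu_E, params.mu_M
    kEM, kME = params.k_EM, params.k_ME
    return np.array(
        [
            [kE - mE - kEM, kME, 0.0, 0.0, 0.0],
            [kEM, kM - mM - kME, 0.0, 0.0, 0.0],
            [kE + mE + kEM, kME, 2.0 * (kE - mE - kEM), 0.0, 2.0 * kME],
            [kEM, kM + mM + kME, 0.0, 2.0 * (kM - mM - kME), 2.0 * kEM],
            [-kEM, -kME, kEM, kME, kE + kM - mE - mM - kEM - kME],
        ]
    )


def _propagate_linear(A: np.ndarray, y0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """y(t) = exp(A t) y0 on a grid, via eigendecomposition with expm fallback."""
    try:
        lam, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            c = Vinv @ y0
            # (nt, n): rows are y(t)
            out = np.real(np.exp(np.outer(t_grid, lam)) * c[None, :] @ V.T)
            check = V @ (lam * Vinv[:, 0])  # cheap reconstruction probe
            if np.allclose(np.real(check), A[:, 0], atol=1e-8 * (1 + np.abs(A).max())):
                return out
    except np.linalg.LinAlgError:
        pass
    return np.stack([expm(A * t) @ y0 for t in t_grid])


def moments_growth(params: RateParameters, E0: float, M0: float, t_grid) -> MomentSummary:
    """First and second moments of (E, M) from a deterministic initial state.

    Solves the closed 5-dimensional linear moment system exactly by matrix
    exponentiation on the requested grid.  Applies to either phase (set the
    birth rates to zero for drug exposure).
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid < 0):
        raise DomainError("t_grid must be non-negative")
    y0 = np.array([E0, M0, E0 * E0, M0 * M0, E0 * M0], dtype=float)
    Y = _propagate_linear(moment_matrix(params), y0, t_grid)
    mE, mM, EE, MM, EM = (Y[:, i] for i in range(5))
    return MomentSummary(
        t=t_grid,
        mean_E=mE,
        mean_M=mM,
        var_E=EE - mE**2,
        var_M=MM - mM**2,
        cov_EM=EM - mE * mM,
        EE=EE,
        MM=MM,
        EM=EM,
    )
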