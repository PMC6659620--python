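"""Moment-based parameter estimation from replicate time-course data.

The estimation protocol mirrors the designed-initial-condition experiments
the model supports:

* drug phase, all-sensitive start (p0 = 0): a three-parameter fit of the
  bi-exponential mean-survival curve yields ``mu_E``, ``gamma0``, ``alpha0``;
* drug phase, all-tolerant start (p0 = 1): a one-parameter fit yields
  ``mu_M``;
* the composite-rate definitions are then inverted algebraically for the
  switching rates ``k_EM``, ``k_ME``;
* a mixed condition supplies, through its mean and Fano factor, closed-form
  estimators of the initial-fraction mean and variance;
* growth phase: mean curves from single-phenotype starts identify only the
  effective birth rates ``kEf = k_E - mu_E`` and ``kMf = k_M - mu_M`` plus
  the switching rates; adding variance trajectories separates births from
  deaths (the variance depends on ``k + mu``, the mean only on ``k - mu``).

All fits are box-constrained least squares with seeded Latin-hypercube
multi-start; uncertainty is nonparametric bootstrap over replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from phenoswitch.analytics import _exp_cosh, _exp_sinch, moments_growth
from phenoswitch.errors import DomainError, IdentifiabilityError, NumericalError
from phenoswitch.model import RateParameters, growth_phase_rates

__all__ = [
    "MomentTimeSeries",
    "EstimationReport",
    "fit_drug_mean_curve",
    "fit_drug_muM",
    "invert_drug_rates",
    "invert_growth_rates",
    "estimate_initial_heterogeneity",
    "fit_growth_mean_curves",
    "fit_growth_full",
    "estimate_drug_protocol",
    "compare_phases",
    "series_from_counts",
]

#: upper bound of the default fitting box (rates per unit time)
RATE_BOX = 10.0


@dataclass
class MomentTimeSeries:
    """Cross-replicate moment trajectory for one experimental condition."""

    times: np.ndarray
    mean_N: np.ndarray
    var_N: np.ndarray | None = None
    N0: int | None = None
    n_samples: np.ndarray | None = None
    label: str = ""
    E0: float | None = None  # known initial counts (growth phase)
    M0: float | None = None
    mean_se: np.ndarray | None = None
    var_se: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_N = np.asarray(self.mean_N, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.mean_N.shape:
            raise DomainError("times and mean_N must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.mean_N < 0):
            raise DomainError("mean_N must be >= 0")
        if self.var_N is not None:
            self.var_N = np.asarray(self.var_N, dtype=float)


@dataclass
class EstimationReport:
    """Point estimates, bootstrap confidence intervals, and diagnostics."""

    estimates: dict = dc_field(default_factory=dict)
    ci: dict = dc_field(default_factory=dict)
    diagnostics: dict = dc_field(default_factory=dict)
    flags: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "ci": {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()},
            "diagnostics": _jsonable(self.diagnostics),
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        lines = [f"{'parameter':<12} {'estimate':>12} {'ci_low':>12} {'ci_high':>12}"]
        for k, v in self.estimates.items():
            lo, hi = self.ci.get(k, (float("nan"), float("nan")))
            lines.append(f"{k:<12} {v:>12.6g} {lo:>12.6g} {hi:>12.6g}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def series_from_counts(
    df: pd.DataFrame, *, N0: int | None = None, label: str = "",
    E0: float | None = None, M0: float | None = None,
) -> MomentTimeSeries:
    """Build a moment series from long-format counts (sample_id, time, N or E/M)."""
    df = df.copy()
    if "N" not in df.columns:
        if not {"E", "M"} <= set(df.columns):
            raise DomainError("counts need an N column or both E and M columns")
        df["N"] = df["E"] + df["M"]
    g = df.groupby("time")["N"]
    times = np.array(sorted(df["time"].unique()), dtype=float)
    mean_N = g.mean().reindex(times).to_numpy()
    var_N = g.var(ddof=1).reindex(times).to_numpy()
    n = g.count().reindex(times).to_numpy()
    return MomentTimeSeries(
        times=times, mean_N=mean_N, var_N=var_N, N0=N0,
        n_samples=n, label=label, E0=E0, M0=M0,
    )


# ---------------------------------------------------------------------------
# drug-phase mean model and fits
# ---------------------------------------------------------------------------

def _drug_mean_fraction(t, mu_bar, g0, a0):
    """Mean surviving fraction <N>/N0 for starting death rate ``mu_bar``.

    ``mu_bar = (1 - p0) mu_E + p0 mu_M``; single-phenotype starts make it
    plain ``mu_E`` (p0 = 0) or ``mu_M`` (p0 = 1).
    """
    t = np.asarray(t, dtype=float)
    x = 0.5 * a0 * t
    u = -0.5 * g0 * t
    return _exp_cosh(u, x) + (g0 - 2.0 * mu_bar) * 0.5 * t * _exp_sinch(u, x)


def _lhs_starts(bounds_lo, bounds_hi, n, seed):
    sampler = qmc.LatinHypercube(d=len(bounds_lo), seed=seed)
    u = sampler.random(n)
    return qmc.scale(u, bounds_lo, bounds_hi)


def _multistart_least_squares(residual, starts, lo, hi, **kw):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), **kw)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise NumericalError("all optimization starts failed")
    return best


def fit_drug_mean_curve(
    series: MomentTimeSeries,
    *,
    n_starts: int = 8,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> EstimationReport:
    """Fit the all-sensitive (p0 = 0) drug-phase mean curve.

    Estimates ``(mu_E, gamma0, alpha0)`` by constrained nonlinear least
    squares on ``mean_N / N0``, parameterized as ``(mu_E, gamma0,
    alpha0/gamma0)`` so the constraint ``alpha0 <= gamma0`` is a plain box.
    ``x0`` skips the multi-start and warm-starts a single fit (used by
    bootstrap refits).
    """
    if series.N0 is None:
        raise DomainError("series.N0 is required for drug-phase fits")
    t, y = series.times, series.mean_N / series.N0
    if t.size < 4:
        raise DomainError("need >= 4 time points for the three-parameter fit")

    def residual(theta):
        mu, g0, frac = theta
        return _drug_mean_fraction(t, mu, g0, frac * g0) - y

    lo = np.array([0.0, 1e-8, 0.0])
    hi = np.array([RATE_BOX, 4.0 * RATE_BOX, 1.0])
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        # data-driven start: early decay slope approximates mu_E
        j = int(np.argmax(t > 0))
        if t[j] > 0 and 0 < y[j] < 1:
            mu_guess = -math.log(y[j]) / t[j]
        else:
            mu_guess = 1e-3
        starts = [np.array([mu_guess, 2.0 * mu_guess, 0.5])]
        starts += list(
            _lhs_starts([0.01, 0.05, 0.05], [3.0, 6.0, 0.95], n_starts - 1, seed)
        )
    sol = _multistart_least_squares(residual, starts, lo, hi, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, g0, frac = sol.x
    a0 = frac * g0
    flags = []
    if not sol.success:
        flags.append("non-convergence")
    for val, lo_b, hi_b, name in zip(sol.x, lo, hi, ("mu_E", "gamma0", "alpha_frac")):
        if name != "alpha_frac" and (abs(val - hi_b) < 1e-9 * (1 + hi_b)):
            flags.append(f"boundary-pinned:{name}")
    r_fast, r_slow = 0.5 * (g0 + a0), 0.5 * (g0 - a0)
    if r_fast > 0 and abs(r_fast - r_slow) < 0.05 * r_fast:
        flags.append("weak-identifiability:near-single-exponential")
    return EstimationReport(
        estimates={"mu_E": mu, "gamma0": g0, "alpha0": a0},
        diagnostics={
            "residual_norm": float(np.linalg.norm(sol.fun)),
            "converged": bool(sol.success),
            "theta": sol.x.tolist(),
        },
        flags=flags,
    )


def fit_drug_muM(
    series: MomentTimeSeries,
    gamma0: float,
    alpha0: float,
    *,
    x0: float | None = None,
) -> EstimationReport:
    """Fit ``mu_M`` from the all-tolerant (p0 = 1) drug-phase mean curve.

    ``gamma0`` and ``alpha0`` are held at their previously estimated values;
    the initial slope of ``mean_N / N0`` (which is exactly ``-mu_M``) seeds
    the one-parameter fit.
    """
    if series.N0 is None:
        raise DomainError("series.N0 is required for drug-phase fits")
    t, y = series.times, series.mean_N / series.N0

    def residual(theta):
        return _drug_mean_fraction(t, theta[0], gamma0, alpha0) - y

    if x0 is None:
        j = int(np.argmax(t > 0))
        x0 = max(1e-3, (1.0 - y[j]) / t[j]) if t[j] > 0 else 1e-3
    sol = least_squares(
        residual, [min(max(x0, 0.0), RATE_BOX)], bounds=([0.0], [RATE_BOX]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    flags = [] if sol.success else ["non-convergence"]
    return EstimationReport(
        estimates={"mu_M": float(sol.x[0])},
        diagnostics={
            "residual_norm": float(np.linalg.norm(sol.fun)),
            "converged": bool(sol.success),
        },
        flags=flags,
    )


def invert_drug_rates(
    gamma0: float, alpha0: float, mu_E: float, mu_M: float, *, tol: float = 1e-9
) -> tuple[float, float]:
    """Recover the switching rates from drug-phase composites and death rates.

    ``k_ME = (gamma0^2 - alpha0^2 - 4 (gamma0 - mu_M) mu_M) / (4 (mu_E - mu_M))``
    and ``k_EM = gamma0 - k_ME - mu_E - mu_M``.  Equal death rates make the
    system structurally non-identifiable.
    """
    if mu_E == mu_M:
        raise IdentifiabilityError(
            "mu_E == mu_M: switching rates are not identifiable from the "
            "drug-phase composites"
        )
    k_ME = (gamma0**2 - alpha0**2 - 4.0 * (gamma0 - mu_M) * mu_M) / (4.0 * (mu_E - mu_M))
    k_EM = gamma0 - k_ME - mu_E - mu_M
    scale = max(1.0, abs(gamma0))
    if k_ME < -tol * scale or k_EM < -tol * scale:
        raise DomainError(
            f"inconsistent inputs: recovered switching rates ({k_EM}, {k_ME}) "
            "are negative"
        )
    return max(k_EM, 0.0), max(k_ME, 0.0)


def invert_growth_rates(
    gammaG: float, alphaG: float, kEf: float, kMf: float, *, tol: float = 1e-9
) -> tuple[float, float]:
    """Recover the switching rates from growth-phase composites.

    Same algebra as :func:`invert_drug_rates` with the effective birth rates
    in place of the negated death rates.
    """
    if kEf == kMf:
        raise IdentifiabilityError(
            "kEf == kMf: switching rates are not identifiable from the "
            "growth-phase composites"
        )
    k_ME = (alphaG**2 - gammaG**2 - 4.0 * (gammaG + kMf) * kMf) / (4.0 * (kEf - kMf))
    k_EM = gammaG + kEf + kMf - k_ME
    scale = max(1.0, abs(gammaG))
    if k_ME < -tol * scale or k_EM < -tol * scale:
        raise DomainError(
            f"inconsistent inputs: recovered switching rates ({k_EM}, {k_ME}) "
            "are negative"
        )
    return max(k_EM, 0.0), max(k_ME, 0.0)


# ---------------------------------------------------------------------------
# initial-heterogeneity estimators
# ---------------------------------------------------------------------------

def estimate_initial_heterogeneity(
    mean_N,
    fano_N,
    mean_N_p0eq0,
    mean_N_p0eq1,
    N0: int,
    n_samples=None,
    *,
    weights=None,
) -> EstimationReport:
    """Closed-form estimators of the initial-fraction mean and variance.

    Per time point,

        p0      = (<N> - <N>_0) / (<N>_1 - <N>_0)
        sigma^2 = N0 <N> / ((<N>_1 - <N>_0)^2 (N0 - 1)) * (F - 1 + <N>/N0)

    where ``<N>_0``/``<N>_1`` are the all-sensitive / all-tolerant reference
    means measured at the same times.  Per-time estimates are combined by
    inverse-variance weights when ``weights`` (per-time variances of the
    estimates, e.g. from a bootstrap) are supplied, otherwise equally.
    Estimates are clipped to their feasible ranges with a flag.
    """
    mean_N = np.atleast_1d(np.asarray(mean_N, float))
    fano_N = np.atleast_1d(np.asarray(fano_N, float))
    m0 = np.atleast_1d(np.asarray(mean_N_p0eq0, float))
    m1 = np.atleast_1d(np.asarray(mean_N_p0eq1, float))
    if N0 < 2:
        raise DomainError("N0 must be >= 2 for the heterogeneity estimator")
    denom = m1 - m0
    usable = np.abs(denom) > 1e-12 * N0
    if not np.any(usable):
        raise IdentifiabilityError(
            "<N>_0 == <N>_1 at every time (mu_E == mu_M): initial "
            "heterogeneity is not identifiable"
        )
    flags = []
    if not np.all(usable):
        flags.append("degenerate-times-skipped")
    p0_t = (mean_N[usable] - m0[usable]) / denom[usable]
    var_t = (
        N0 * mean_N[usable] / (denom[usable] ** 2 * (N0 - 1.0))
        * (fano_N[usable] - 1.0 + mean_N[usable] / N0)
    )
    if weights is not None:
        w_p, w_v = (np.atleast_1d(np.asarray(w, float))[usable] for w in weights)
        w_p = np.where(w_p > 0, 1.0 / w_p, 0.0)
        w_v = np.where(w_v > 0, 1.0 / w_v, 0.0)
        if w_p.sum() == 0:
            w_p = np.ones_like(w_p)
        if w_v.sum() == 0:
            w_v = np.ones_like(w_v)
    else:
        w_p = np.ones_like(p0_t)
        w_v = np.ones_like(var_t)
    p0 = float(np.sum(w_p * p0_t) / np.sum(w_p))
    var = float(np.sum(w_v * var_t) / np.sum(w_v))
    if not 0.0 <= p0 <= 1.0:
        flags.append("clipped:p0_mean")
        p0 = min(max(p0, 0.0), 1.0)
    var_max = p0 * (1.0 - p0)
    if var < 0.0:
        flags.append("negative-variance-clipped")
        var = 0.0
    elif var > var_max:
        flags.append("clipped:p0_var")
        var = var_max
    return EstimationReport(
        estimates={"p0_mean": p0, "p0_var": var},
        diagnostics={
            "per_time_p0": p0_t.tolist(),
            "per_time_var": var_t.tolist(),
            "n_samples": _jsonable(n_samples),
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# growth-phase fits
# ---------------------------------------------------------------------------

def _growth_mean_theta(t, E0, M0, theta):
    kEf, kMf, kEM, kME = theta
    g = kEM + kME - kEf - kMf
    disc = g * g + 4.0 * (kME * (kEf - kMf) + (g + kMf) * kMf)
    a = math.sqrt(max(disc, 0.0))
    x = 0.5 * a * t
    u = -0.5 * g * t
    slope = E0 * (g + 2.0 * kEf) + M0 * (g + 2.0 * kMf)
    return (E0 + M0) * _exp_cosh(u, x) + slope * 0.5 * t * _exp_sinch(u, x)


def fit_growth_mean_curves(
    series_E0only: MomentTimeSeries,
    series_M0only: MomentTimeSeries,
    *,
    n_starts: int = 8,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> EstimationReport:
    """Joint fit of the two single-phenotype growth-phase mean curves.

    Identifies the effective birth rates and the switching rates (the only
    combinations the mean dynamics see); the composites ``gammaG``/``alphaG``
    are reported alongside.  Individual births and deaths are *not*
    identifiable from means alone.
    """
    sE, sM = series_E0only, series_M0only
    if sE.E0 is None or sM.M0 is None:
        raise DomainError("series must declare their known initial counts E0/M0")
    scale_E = max(sE.mean_N.max(), 1.0)
    scale_M = max(sM.mean_N.max(), 1.0)

    def residual(theta):
        rE = (_growth_mean_theta(sE.times, sE.E0, 0.0, theta) - sE.mean_N) / scale_E
        rM = (_growth_mean_theta(sM.times, 0.0, sM.M0, theta) - sM.mean_N) / scale_M
        return np.concatenate([rE, rM])

    lo = np.array([-RATE_BOX, -RATE_BOX, 0.0, 0.0])
    hi = np.array([RATE_BOX, RATE_BOX, RATE_BOX, RATE_BOX])
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        # crude per-curve exponential-rate guesses for the effective rates
        gE = math.log(max(sE.mean_N[-1], 1e-9) / sE.E0) / sE.times[-1]
        gM = math.log(max(sM.mean_N[-1], 1e-9) / sM.M0) / sM.times[-1]
        starts = [np.array([gE, gM, 0.1, 0.1])]
        starts += list(
            _lhs_starts([-2.0, -2.0, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0], n_starts - 1, seed)
        )
    sol = _multistart_least_squares(residual, starts, lo, hi, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kEf, kMf, kEM, kME = sol.x
    g = kEM + kME - kEf - kMf
    disc = g * g + 4.0 * (kME * (kEf - kMf) + (g + kMf) * kMf)
    flags = [] if sol.success else ["non-convergence"]
    if abs(kEf - kMf) < 1e-6:
        flags.append("weak-identifiability:kEf~kMf")
    return EstimationReport(
        estimates={
            "kEf": kEf, "kMf": kMf, "k_EM": kEM, "k_ME": kME,
            "gammaG": g, "alphaG": math.sqrt(max(disc, 0.0)),
        },
        diagnostics={
            "residual_norm": float(np.linalg.norm(sol.fun)),
            "converged": bool(sol.success),
        },
        flags=flags,
    )


def fit_growth_full(
    series: MomentTimeSeries | list[MomentTimeSeries],
    *,
    init_composites: EstimationReport | None = None,
    n_starts: int = 8,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> EstimationReport:
    """Fit all six rates from growth-phase mean *and* variance trajectories.

    Accepts one or more conditions with known deterministic initial states.
    Residuals combine means and variances, each scaled by its own magnitude
    (or by supplied standard errors); the variance information is what
    separates ``k_E`` from ``mu_E`` and ``k_M`` from ``mu_M``.
    """
    series_list = series if isinstance(series, (list, tuple)) else [series]
    for s in series_list:
        if s.E0 is None or s.M0 is None:
            raise DomainError("each series needs known initial counts (E0, M0)")
        if s.var_N is None:
            raise DomainError("fit_growth_full needs variance trajectories")

    def residual(theta):
        params = RateParameters(*theta)
        out = []
        for s in series_list:
            ms = moments_growth(params, s.E0, s.M0, s.times)
            w_mean = s.mean_se if s.mean_se is not None else max(s.mean_N.max(), 1.0)
            w_var = s.var_se if s.var_se is not None else max(s.var_N.max(), 1.0)
            out.append((ms.mean_N - s.mean_N) / w_mean)
            out.append((ms.var_N - s.var_N) / w_var)
        return np.concatenate(out)

    lo = np.zeros(6)
    hi = np.full(6, RATE_BOX)
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        starts = []
        if init_composites is not None:
            est = init_composites.estimates
            for mu_E in (0.05, 0.3, 1.0):
                for mu_M in (0.05, 0.3, 1.0):
                    starts.append(
                        np.array([
                            est["kEf"] + mu_E, est["kMf"] + mu_M, mu_E, mu_M,
                            est["k_EM"], est["k_ME"],
                        ])
                    )
        starts += list(
            _lhs_starts([0.0] * 6, [2.0] * 6, max(n_starts - len(starts), 2), seed)
        )
    sol = _multistart_least_squares(residual, starts, lo, hi, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kE, kM, mE, mM, kEM, kME = sol.x
    params = RateParameters(kE, kM, mE, mM, kEM, kME)
    comp = growth_phase_rates(params)
    flags = [] if sol.success else ["non-convergence"]
    # with SE-weighted residuals the expected norm is ~sqrt(dof)
    if float(np.linalg.norm(sol.fun)) > 3.0 * math.sqrt(sol.fun.size):
        flags.append("poor-fit:large-residual")
    return EstimationReport(
        estimates={
            "k_E": kE, "k_M": kM, "mu_E": mE, "mu_M": mM,
            "k_EM": kEM, "k_ME": kME,
            "kEf": comp.kEf, "kMf": comp.kMf,
            "gammaG": comp.gammaG, "alphaG": comp.alphaG,
        },
        diagnostics={
            "residual_norm": float(np.linalg.norm(sol.fun)),
            "converged": bool(sol.success),
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# full drug-phase protocol with bootstrap
# ---------------------------------------------------------------------------

def _protocol_point(times, N0, y0_mean, y1_mean, ym_mean, ym_fano, *, seed=0,
                    x0_curve=None, x0_muM=None, het_weights=None):
    """One pass of the three-condition drug-phase estimation chain."""
    s0 = MomentTimeSeries(times=times, mean_N=y0_mean, N0=N0, label="p0=0")
    rep0 = fit_drug_mean_curve(s0, seed=seed, x0=x0_curve)
    mu_E = rep0.estimates["mu_E"]
    g0 = rep0.estimates["gamma0"]
    a0 = rep0.estimates["alpha0"]
    s1 = MomentTimeSeries(times=times, mean_N=y1_mean, N0=N0, label="p0=1")
    rep1 = fit_drug_muM(s1, g0, a0, x0=x0_muM)
    mu_M = rep1.estimates["mu_M"]
    try:
        k_EM, k_ME = invert_drug_rates(g0, a0, mu_E, mu_M, tol=1e-3)
    except (DomainError, IdentifiabilityError):
        k_EM = k_ME = float("nan")
    mask = times > 0
    het = estimate_initial_heterogeneity(
        ym_mean[mask], ym_fano[mask], y0_mean[mask], y1_mean[mask], N0,
        weights=het_weights,
    )
    return {
        "mu_E": mu_E, "mu_M": mu_M, "gamma0": g0, "alpha0": a0,
        "k_EM": k_EM, "k_ME": k_ME,
        "p0_mean": het.estimates["p0_mean"], "p0_var": het.estimates["p0_var"],
    }, rep0, het


def estimate_drug_protocol(
    counts_p0: np.ndarray,
    counts_p1: np.ndarray,
    counts_mixed: np.ndarray,
    times: np.ndarray,
    N0: int,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EstimationReport:
    """Run the full three-initial-condition drug-phase protocol.

    ``counts_*`` are (replicates x times) total-count matrices for the
    all-sensitive, all-tolerant, and mixed conditions on a shared time grid.
    Point estimates come from the estimation chain on cross-replicate
    moments; percentile confidence intervals come from a seeded nonparametric
    bootstrap over replicates (each resample refits the chain, warm-started
    at the point estimates).
    """
    times = np.asarray(times, dtype=float)
    mats = [np.asarray(c, dtype=float) for c in (counts_p0, counts_p1, counts_mixed)]
    for c in mats:
        if c.ndim != 2 or c.shape[1] != times.size:
            raise DomainError("count matrices must be (replicates x times)")
    c0, c1, cm = mats

    def summarize(c):
        m = c.mean(axis=0)
        v = c.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(m > 0, v / m, np.nan)
        return m, f

    m0, _ = summarize(c0)
    m1, _ = summarize(c1)
    mm, fm = summarize(cm)

    # pilot bootstrap for the per-time heterogeneity weights
    rng = np.random.default_rng(seed)
    mask = times > 0
    n_pilot = min(100, max(n_boot, 1))
    pilot_p0 = np.empty((n_pilot, int(mask.sum())))
    pilot_var = np.empty_like(pilot_p0)
    for b in range(n_pilot):
        bm0 = c0[rng.integers(0, c0.shape[0], c0.shape[0])].mean(axis=0)
        bm1 = c1[rng.integers(0, c1.shape[0], c1.shape[0])].mean(axis=0)
        cmb = cm[rng.integers(0, cm.shape[0], cm.shape[0])]
        bmm = cmb.mean(axis=0)
        bvv = cmb.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bff = np.where(bmm > 0, bvv / bmm, np.nan)
        d = bm1[mask] - bm0[mask]
        pilot_p0[b] = (bmm[mask] - bm0[mask]) / d
        pilot_var[b] = (
            N0 * bmm[mask] / (d**2 * (N0 - 1.0)) * (bff[mask] - 1.0 + bmm[mask] / N0)
        )
    het_weights = (np.var(pilot_p0, axis=0), np.var(pilot_var, axis=0))

    point, rep0, het = _protocol_point(
        times, N0, m0, m1, mm, fm, seed=seed, het_weights=het_weights
    )

    x0_curve = np.array([
        point["mu_E"], point["gamma0"],
        point["alpha0"] / max(point["gamma0"], 1e-12),
    ])
    x0_muM = point["mu_M"]

    keys = list(point)
    boots = {k: [] for k in keys}
    for b in range(n_boot):
        b0 = c0[rng.integers(0, c0.shape[0], c0.shape[0])]
        b1 = c1[rng.integers(0, c1.shape[0], c1.shape[0])]
        bm = cm[rng.integers(0, cm.shape[0], cm.shape[0])]
        bm0, _ = summarize(b0)
        bm1, _ = summarize(b1)
        bmm, bfm = summarize(bm)
        try:
            bp, _, _ = _protocol_point(
                times, N0, bm0, bm1, bmm, bfm, seed=seed,
                x0_curve=x0_curve, x0_muM=x0_muM, het_weights=het_weights,
            )
        except (NumericalError, IdentifiabilityError, DomainError):
            continue
        for k in keys:
            boots[k].append(bp[k])

    q = 0.5 * (1.0 - ci_level)
    ci = {}
    for k in keys:
        vals = np.asarray(boots[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= 10:
            ci[k] = (float(np.quantile(vals, q)), float(np.quantile(vals, 1.0 - q)))
        else:
            ci[k] = (float("nan"), float("nan"))

    return EstimationReport(
        estimates=point,
        ci=ci,
        diagnostics={
            "n_boot_effective": int(len(boots["mu_E"])),
            "curve_fit": rep0.diagnostics,
            "heterogeneity": het.diagnostics,
        },
        flags=rep0.flags + het.flags,
    )


def _growth_series(counts: np.ndarray, times: np.ndarray, E0: float, M0: float,
                   label: str = "") -> MomentTimeSeries:
    """Moment series with moment-based SE weights from a count matrix."""
    n = counts.shape[0]
    mean_N = counts.mean(axis=0)
    var_N = counts.var(axis=0, ddof=1)
    mean_se = np.sqrt(np.maximum(var_N, 1e-12) / n)
    var_se = np.maximum(var_N, 1e-6) * math.sqrt(2.0 / max(n - 1, 1))
    return MomentTimeSeries(
        times=times, mean_N=mean_N, var_N=var_N, E0=E0, M0=M0,
        mean_se=mean_se, var_se=var_se, label=label, n_samples=np.full(times.size, n),
    )


def estimate_growth_protocol(
    counts_E0only: np.ndarray,
    counts_M0only: np.ndarray,
    times: np.ndarray,
    E0: float,
    M0: float,
    *,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EstimationReport:
    """Growth-phase protocol: mean-curve fit, then the full six-rate fit.

    ``counts_*`` are (replicates x times) total-count matrices from the two
    single-phenotype starts.  Mean/variance residuals are weighted by
    moment-based standard errors; percentile confidence intervals come from
    a seeded bootstrap over replicates with warm-started refits.
    """
    times = np.asarray(times, dtype=float)
    cE = np.asarray(counts_E0only, dtype=float)
    cM = np.asarray(counts_M0only, dtype=float)
    mask = times > 0  # t=0 has zero variance under deterministic starts
    tt = times[mask]

    def build(cE_, cM_):
        sE = _growth_series(cE_[:, mask], tt, E0, 0.0, "E0-only")
        sM = _growth_series(cM_[:, mask], tt, 0.0, M0, "M0-only")
        return sE, sM

    sE, sM = build(cE, cM)
    rep_means = fit_growth_mean_curves(sE, sM, seed=seed)
    point = fit_growth_full([sE, sM], init_composites=rep_means, seed=seed)
    x0 = np.array([point.estimates[k] for k in ("k_E", "k_M", "mu_E", "mu_M", "k_EM", "k_ME")])

    rng = np.random.default_rng(seed)
    keys = ("k_E", "k_M", "mu_E", "mu_M", "k_EM", "k_ME", "kEf", "kMf")
    boots = {k: [] for k in keys}
    for _ in range(n_boot):
        bE = cE[rng.integers(0, cE.shape[0], cE.shape[0])]
        bM = cM[rng.integers(0, cM.shape[0], cM.shape[0])]
        try:
            sEb, sMb = build(bE, bM)
            rb = fit_growth_full([sEb, sMb], x0=x0)
        except (NumericalError, DomainError):
            continue
        for k in keys:
            boots[k].append(rb.estimates[k])

    q = 0.5 * (1.0 - ci_level)
    ci = {}
    for k in keys:
        vals = np.asarray(boots[k], dtype=float)
        if vals.size >= 10:
            ci[k] = (float(np.quantile(vals, q)), float(np.quantile(vals, 1.0 - q)))
        else:
            ci[k] = (float("nan"), float("nan"))
    point.ci = ci
    point.diagnostics["n_boot_effective"] = int(len(boots["k_E"]))
    point.diagnostics["mean_curve_fit"] = rep_means.estimates
    return point


# ---------------------------------------------------------------------------
# phase comparison
# ---------------------------------------------------------------------------

def _ci_disjoint(ci_a, ci_b) -> bool:
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def compare_phases(report_pre: EstimationReport, report_post: EstimationReport) -> dict:
    """Label the adaptation-versus-selection signature across phases.

    Compares the switching-rate confidence intervals of pre-drug (growth) and
    post-drug estimates, and whether the death rates increased.  Emits a
    labeled summary, not a hypothesis test.
    """
    out = {"switching": {}, "deaths": {}, "label": "inconclusive"}
    switching_changed = False
    for k in ("k_EM", "k_ME"):
        ci_pre = report_pre.ci.get(k)
        ci_post = report_post.ci.get(k)
        if ci_pre is None or ci_post is None:
            out["switching"][k] = "no-interval"
            continue
        disjoint = _ci_disjoint(ci_pre, ci_post)
        out["switching"][k] = "changed" if disjoint else "consistent"
        switching_changed = switching_changed or disjoint
    deaths_increased = False
    for k in ("mu_E", "mu_M"):
        pre = report_pre.estimates.get(k)
        post = report_post.estimates.get(k)
        if pre is None or post is None:
            out["deaths"][k] = "unavailable"
            continue
        ci_pre = report_pre.ci.get(k, (pre, pre))
        ci_post = report_post.ci.get(k, (post, post))
        up = post > pre and ci_post[0] > ci_pre[1]
        out["deaths"][k] = "increased" if up else "unchanged"
        deaths_increased = deaths_increased or up
    if switching_changed:
        out["label"] = "adaptation-indicated"
    elif deaths_increased:
        out["label"] = "selection-dominant"
    return out
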