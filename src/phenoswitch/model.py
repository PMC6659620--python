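"""Model parameters, composite rates, and shared state types.

The kinetic model has two cell phenotypes: drug-sensitive E cells and
drug-tolerant M cells.  Six non-negative rate constants govern the dynamics:
per-state birth rates ``k_E``/``k_M``, death rates ``mu_E``/``mu_M``, and
switching rates ``k_EM`` (E to M) and ``k_ME`` (M to E).  All rates are plain
non-negative reals in a user-declared time unit; no unit conversion is
attempted.

Two composite-rate pairs control the bi-exponential mean dynamics:

* drug phase (births suppressed): ``gamma0`` (sum rate) and ``alpha0``
  (eigenvalue gap), with single-cell rate-matrix eigenvalues
  ``-(gamma0 +/- alpha0) / 2``;
* growth phase: ``gammaG`` and ``alphaG`` playing the same roles for the
  mean-field matrix built from the effective birth rates
  ``kEf = k_E - mu_E`` and ``kMf = k_M - mu_M``.

The growth-phase composites are deliberately named ``gammaG``/``alphaG`` so
they cannot be confused with the Beta-distribution exponents ``a``/``b`` used
elsewhere in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from phenoswitch.errors import DomainError, NumericalError

__all__ = [
    "RateParameters",
    "DrugPhaseRates",
    "GrowthPhaseRates",
    "InitialComposition",
    "PopulationState",
    "drug_phase_rates",
    "growth_phase_rates",
]

#: discriminants in [-_DISC_CLAMP, 0) are treated as round-off zeros
_DISC_CLAMP = 1e-12


@dataclass(frozen=True)
class RateParameters:
    """The six kinetic constants of the two-phenotype model.

    Parameters
    ----------
    k_E, k_M
        Birth rates of E and M cells (per cell per unit time).
    mu_E, mu_M
        Death rates of E and M cells.
    k_EM, k_ME
        Switching rates E->M and M->E.
    """

    k_E: float
    k_M: float
    mu_E: float
    mu_M: float
    k_EM: float
    k_ME: float

    def __post_init__(self) -> None:
        for name in ("k_E", "k_M", "mu_E", "mu_M", "k_EM", "k_ME"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"rate {name}={v!r} must be finite and >= 0")

    def without_births(self) -> "RateParameters":
        """Return a copy with ``k_E = k_M = 0`` (drug-phase convention)."""
        return RateParameters(0.0, 0.0, self.mu_E, self.mu_M, self.k_EM, self.k_ME)

    def scaled(self, c: float) -> "RateParameters":
        """Return a copy with every rate multiplied by ``c`` (time rescaling)."""
        return RateParameters(
            c * self.k_E, c * self.k_M, c * self.mu_E,
            c * self.mu_M, c * self.k_EM, c * self.k_ME,
        )

    def to_dict(self) -> dict:
        return {
            "k_E": self.k_E, "k_M": self.k_M,
            "mu_E": self.mu_E, "mu_M": self.mu_M,
            "k_EM": self.k_EM, "k_ME": self.k_ME,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        try:
            return cls(
                k_E=float(d["k_E"]), k_M=float(d["k_M"]),
                mu_E=float(d["mu_E"]), mu_M=float(d["mu_M"]),
                k_EM=float(d["k_EM"]), k_ME=float(d["k_ME"]),
            )
        except KeyError as e:  # pragma: no cover - trivial plumbing
            raise DomainError(f"missing rate parameter {e.args[0]!r}") from e

    @classmethod
    def from_json(cls, path) -> "RateParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class DrugPhaseRates:
    """Composite rates of the drug phase: sum rate and eigenvalue gap."""

    gamma0: float
    alpha0: float

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """Eigenvalues ``(-(gamma0+alpha0)/2, -(gamma0-alpha0)/2)``."""
        return (-(self.gamma0 + self.alpha0) / 2.0, -(self.gamma0 - self.alpha0) / 2.0)


@dataclass(frozen=True)
class GrowthPhaseRates:
    """Composite rates of the growth phase plus the effective birth rates."""

    gammaG: float
    alphaG: float
    kEf: float
    kMf: float

    @property
    def eigenvalues(self) -> tuple[float, float]:
        return (-(self.gammaG + self.alphaG) / 2.0, -(self.gammaG - self.alphaG) / 2.0)


@dataclass(frozen=True)
class PopulationState:
    """Integer cell counts at a time point."""

    E: int
    M: int
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.E < 0 or self.M < 0 or self.t < 0:
            raise DomainError(f"invalid state E={self.E}, M={self.M}, t={self.t}")

    @property
    def N(self) -> int:
        return self.E + self.M


P0Spec = Union[float, tuple, Sequence[float], dict]


@dataclass(frozen=True)
class InitialComposition:
    """Initial sample of ``N0`` cells with a tolerant fraction specification.

    ``p0`` may be a fixed scalar in [0, 1], a Beta distribution given as
    ``("beta", a, b)``, or an empirical sample of fractions given as
    ``("empirical", [f1, f2, ...])``.  ``mode`` selects how a drawn fraction
    is converted to integer counts: ``"binomial"`` draws
    ``M0 ~ Binomial(N0, p0)`` (the i.i.d.-cell structure of the model),
    ``"deterministic"`` rounds ``N0 * p0``.
    """

    N0: int
    p0: P0Spec = 0.0
    mode: str = "binomial"
    _beta: tuple = field(default=None, repr=False, compare=False)
    _empirical: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if int(self.N0) != self.N0 or self.N0 < 1:
            raise DomainError(f"N0={self.N0!r} must be an integer >= 1")
        if self.mode not in ("binomial", "deterministic"):
            raise DomainError(f"unknown composition mode {self.mode!r}")
        object.__setattr__(self, "N0", int(self.N0))
        kind, payload = _parse_p0_spec(self.p0)
        if kind == "beta":
            object.__setattr__(self, "_beta", payload)
        elif kind == "empirical":
            object.__setattr__(self, "_empirical", payload)
        else:
            object.__setattr__(self, "p0", payload)

    @property
    def kind(self) -> str:
        if self._beta is not None:
            return "beta"
        if self._empirical is not None:
            return "empirical"
        return "fixed"

    @property
    def p0_mean(self) -> float:
        """Mean of the tolerant-fraction specification."""
        if self._beta is not None:
            a, b = self._beta
            return a / (a + b)
        if self._empirical is not None:
            return float(np.mean(self._empirical))
        return float(self.p0)

    @property
    def p0_var(self) -> float:
        """Variance of the tolerant-fraction specification."""
        if self._beta is not None:
            a, b = self._beta
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self._empirical is not None:
            return float(np.var(self._empirical))
        return 0.0

    def sample_p0(self, rng: np.random.Generator, size=None):
        """Draw fraction(s) from the specification."""
        if self._beta is not None:
            a, b = self._beta
            return rng.beta(a, b, size=size)
        if self._empirical is not None:
            return rng.choice(self._empirical, size=size, replace=True)
        if size is None:
            return float(self.p0)
        return np.full(size, float(self.p0))

    def to_dict(self) -> dict:
        if self._beta is not None:
            p0 = {"beta": list(self._beta)}
        elif self._empirical is not None:
            p0 = {"empirical": [float(x) for x in self._empirical]}
        else:
            p0 = float(self.p0)
        return {"N0": self.N0, "p0": p0, "mode": self.mode}

    @classmethod
    def from_dict(cls, d: dict) -> "InitialComposition":
        return cls(N0=d["N0"], p0=d.get("p0", 0.0), mode=d.get("mode", "binomial"))

    @classmethod
    def from_json(cls, path) -> "InitialComposition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _parse_p0_spec(spec):
    """Normalize the polymorphic p0 specification; returns (kind, payload)."""
    if isinstance(spec, dict):
        if "beta" in spec:
            spec = ("beta", *spec["beta"])
        elif "empirical" in spec:
            spec = ("empirical", spec["empirical"])
        else:
            raise DomainError(f"unrecognized p0 specification {spec!r}")
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        p = float(spec)
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"fixed p0={p} outside [0, 1]")
        return "fixed", p
    if isinstance(spec, tuple) and len(spec) >= 1 and spec[0] == "beta":
        if len(spec) != 3:
            raise DomainError("beta p0 spec must be ('beta', a, b)")
        a, b = float(spec[1]), float(spec[2])
        if a <= 0 or b <= 0:
            raise DomainError(f"Beta exponents must be positive, got ({a}, {b})")
        return "beta", (a, b)
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "empirical":
        spec = spec[1]
    arr = np.asarray(spec, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError(f"empirical p0 sample must be a non-empty 1-d sequence")
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("empirical p0 values must lie in [0, 1]")
    return "empirical", arr


def _safe_sqrt_disc(disc: float) -> float:
    """sqrt of a discriminant, clamping tiny negative round-off to zero."""
    if disc < 0.0:
        if disc >= -_DISC_CLAMP:
            return 0.0
        raise NumericalError(
            f"discriminant {disc} is negative beyond round-off tolerance; "
            "inputs are inconsistent"
        )
    return math.sqrt(disc)


def drug_phase_rates(params: RateParameters) -> DrugPhaseRates:
    """Composite rates of the drug phase (births suppressed).

    ``gamma0 = k_EM + k_ME + mu_E + mu_M`` and ``alpha0`` is the square root
    of ``gamma0**2 - 4*(k_ME*(mu_E - mu_M) + (gamma0 - mu_M)*mu_M)``, the gap
    between the eigenvalues of the single-cell rate matrix
    ``[[-(k_EM + mu_E), k_ME], [k_EM, -(k_ME + mu_M)]]``.
    """
    g0 = params.k_EM + params.k_ME + params.mu_E + params.mu_M
    disc = g0 * g0 - 4.0 * (
        params.k_ME * (params.mu_E - params.mu_M) + (g0 - params.mu_M) * params.mu_M
    )
    return DrugPhaseRates(gamma0=g0, alpha0=_safe_sqrt_disc(disc))


def growth_phase_rates(params: RateParameters) -> GrowthPhaseRates:
    """Composite rates of the growth phase.

    ``gammaG = k_EM + k_ME - kEf - kMf`` with effective birth rates
    ``kEf = k_E - mu_E`` and ``kMf = k_M - mu_M``; ``alphaG`` is the
    eigenvalue gap of the mean-field matrix
    ``[[kEf - k_EM, k_ME], [k_EM, kMf - k_ME]]``.
    """
    kEf = params.k_E - params.mu_E
    kMf = params.k_M - params.mu_M
    g = params.k_EM + params.k_ME - kEf - kMf
    disc = g * g + 4.0 * (params.k_ME * (kEf - kMf) + (g + kMf) * kMf)
    return GrowthPhaseRates(gammaG=g, alphaG=_safe_sqrt_disc(disc), kEf=kEf, kMf=kMf)
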