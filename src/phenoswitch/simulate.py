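"""Exact stochastic simulation of the two-phenotype birth-death-switching model.

Direct-method Gillespie over six reaction channels:

    E -> 2E   (k_E * E)        M -> 2M   (k_M * M)
    E -> 0    (mu_E * E)       M -> 0    (mu_M * M)
    E -> M    (k_EM * E)       M -> E    (k_ME * M)

States are recorded on a fixed time grid as a right-continuous step function
(the value at a grid point includes every event at times <= that point).
Seeding is deterministic: a master seed is expanded into one 32-bit stream
seed per replicate through ``numpy.random.SeedSequence(master).generate_state``,
so an ensemble is bit-reproducible from (params, init, master seed, grid).

The inner loop is JIT-compiled with numba; a pure-Python twin with identical
event logic and RNG consumption is kept for environments where compilation is
unavailable (``PHENOSWITCH_NO_NUMBA=1``).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phenoswitch.errors import DomainError
from phenoswitch.model import InitialComposition, RateParameters

__all__ = [
    "EnsembleResult",
    "FractionDistribution",
    "draw_initial_composition",
    "ssa_trajectory",
    "simulate_ensemble",
    "ensemble_summary",
    "empirical_fraction_distribution",
]


def _ssa_core_py(kE, kM, muE, muM, kEM, kME, E0, M0, t_grid, seed, out_E, out_M):
    np.random.seed(seed)
    E = E0
    M = M0
    t = 0.0
    n = t_grid.shape[0]
    gi = 0
    while True:
        a1 = kE * E
        a2 = kM * M
        a3 = muE * E
        a4 = muM * M
        a5 = kEM * E
        a6 = kME * M
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            while gi < n:
                out_E[gi] = E
                out_M[gi] = M
                gi += 1
            return
        t_next = t + (-math.log(np.random.random()) / a0)
        while gi < n and t_grid[gi] < t_next:
            out_E[gi] = E
            out_M[gi] = M
            gi += 1
        if gi >= n:
            return
        t = t_next
        r = np.random.random() * a0
        if r < a1:
            E += 1
        elif r < a1 + a2:
            M += 1
        elif r < a1 + a2 + a3:
            E -= 1
        elif r < a1 + a2 + a3 + a4:
            M -= 1
        elif r < a1 + a2 + a3 + a4 + a5:
            E -= 1
            M += 1
        else:
            M -= 1
            E += 1


if os.environ.get("PHENOSWITCH_NO_NUMBA"):
    _ssa_core = _ssa_core_py
else:  # pragma: no branch
    import numba

    _ssa_core = numba.njit(cache=True)(_ssa_core_py)


@dataclass
class EnsembleResult:
    """Seeded SSA replicate trajectories sampled on a common time grid."""

    params: RateParameters
    init: InitialComposition
    t_grid: np.ndarray
    seeds: np.ndarray  # per-replicate stream seeds (uint32)
    E: np.ndarray  # (n_replicates, n_grid) int64
    M: np.ndarray
    master_seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return self.E.shape[0]

    @property
    def N(self) -> np.ndarray:
        return self.E + self.M

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectories: sample_id, time, E, M."""
        n_rep, n_t = self.E.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(np.arange(n_rep), n_t),
                "time": np.tile(self.t_grid, n_rep),
                "E": self.E.ravel(),
                "M": self.M.ravel(),
            }
        )

    def provenance(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "init": self.init.to_dict(),
            "t_grid": [float(t) for t in self.t_grid],
            "master_seed": self.master_seed,
            "n_replicates": self.n_replicates,
        }


@dataclass
class FractionDistribution:
    """Empirical distribution of the tolerant fraction p = M/(E+M) at a time."""

    t: float
    fractions: np.ndarray
    n_extinct: int

    @property
    def n_replicates(self) -> int:
        return self.fractions.size + self.n_extinct

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def variance(self) -> float:
        return float(np.var(self.fractions, ddof=1)) if self.fractions.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.arange(self.fractions.size),
                "time": self.t,
                "fraction": self.fractions,
            }
        )


def draw_initial_composition(
    init: InitialComposition, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw an integer initial state (E0, M0) from the composition spec.

    A fraction p0 is drawn from the spec; in ``binomial`` mode each of the N0
    cells is independently M-type with probability p0, in ``deterministic``
    mode ``M0 = round(N0 * p0)``.
    """
    p0 = float(init.sample_p0(rng))
    if init.mode == "binomial":
        M0 = int(rng.binomial(init.N0, p0))
    else:
        M0 = int(round(init.N0 * p0))
    return init.N0 - M0, M0


def ssa_trajectory(
    params: RateParameters, E0: int, M0: int, t_grid, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One exact SSA path recorded on ``t_grid``; returns (t, E, M) arrays."""
    t_grid = np.ascontiguousarray(t_grid, dtype=np.float64)
    _check_grid(t_grid)
    if E0 < 0 or M0 < 0:
        raise DomainError(f"initial counts must be >= 0, got ({E0}, {M0})")
    out_E = np.empty(t_grid.shape[0], dtype=np.int64)
    out_M = np.empty(t_grid.shape[0], dtype=np.int64)
    _ssa_core(
        params.k_E, params.k_M, params.mu_E, params.mu_M,
        params.k_EM, params.k_ME,
        int(E0), int(M0), t_grid, int(seed) & 0xFFFFFFFF, out_E, out_M,
    )
    return t_grid, out_E, out_M


def _check_grid(t_grid: np.ndarray) -> None:
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise DomainError("t_grid must be a non-empty 1-d array")
    if t_grid[0] != 0.0:
        raise DomainError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing")


def replicate_seeds(master_seed: int, n_replicates: int) -> np.ndarray:
    """Expand a master seed into per-replicate uint32 stream seeds."""
    return np.random.SeedSequence(master_seed).generate_state(n_replicates)


def simulate_ensemble(
    params: RateParameters,
    init: InitialComposition,
    t_grid,
    n_replicates: int,
    seed: int,
) -> EnsembleResult:
    """Run a seeded SSA ensemble.

    The master seed drives both the initial-composition draws (via a
    ``default_rng`` on a child ``SeedSequence``) and the per-replicate SSA
    stream seeds, so the whole ensemble is reproducible bit-exactly.
    """
    t_grid = np.ascontiguousarray(t_grid, dtype=np.float64)
    _check_grid(t_grid)
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = ss.generate_state(n_replicates)
    n_t = t_grid.shape[0]
    E = np.empty((n_replicates, n_t), dtype=np.int64)
    M = np.empty((n_replicates, n_t), dtype=np.int64)
    for i in range(n_replicates):
        E0, M0 = draw_initial_composition(init, init_rng)
        _ssa_core(
            params.k_E, params.k_M, params.mu_E, params.mu_M,
            params.k_EM, params.k_ME,
            E0, M0, t_grid, int(seeds[i]), E[i], M[i],
        )
    return EnsembleResult(
        params=params, init=init, t_grid=t_grid, seeds=seeds, E=E, M=M,
        master_seed=seed,
    )


def ensemble_summary(
    ensemble: EnsembleResult,
    n_boot: int = 1000,
    boot_seed: int = 0,
):
    """Unbiased cross-replicate sample moments per grid time.

    Returns a :class:`~phenoswitch.analytics.MomentSummary` whose ``fano_se``
    field carries seeded bootstrap standard errors of the Fano factor
    (replicates resampled jointly across the grid).
    """
    from phenoswitch.analytics import MomentSummary

    if ensemble.n_replicates < 2:
        raise DomainError("ensemble_summary requires >= 2 replicates")
    E = ensemble.E.astype(float)
    M = ensemble.M.astype(float)
    n = ensemble.n_replicates
    mean_E = E.mean(axis=0)
    mean_M = M.mean(axis=0)
    var_E = E.var(axis=0, ddof=1)
    var_M = M.var(axis=0, ddof=1)
    cov_EM = ((E - mean_E) * (M - mean_M)).sum(axis=0) / (n - 1)

    fano_se = None
    if n_boot > 0:
        rng = np.random.default_rng(boot_seed)
        N = E + M
        boots = np.empty((n_boot, ensemble.t_grid.size))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            Nb = N[idx]
            mb = Nb.mean(axis=0)
            vb = Nb.var(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                boots[b] = np.where(mb > 0, vb / mb, np.nan)
        fano_se = np.nanstd(boots, axis=0, ddof=1)

    return MomentSummary(
        t=ensemble.t_grid,
        mean_E=mean_E, mean_M=mean_M,
        var_E=var_E, var_M=var_M, cov_EM=cov_EM,
        fano_se=fano_se,
    )


def empirical_fraction_distribution(ensemble: EnsembleResult, t: float) -> FractionDistribution:
    """Tolerant fractions p = M/(E+M) over surviving replicates at grid time t."""
    hits = np.flatnonzero(np.isclose(ensemble.t_grid, t))
    if hits.size == 0:
        raise DomainError(f"time {t} is not on the ensemble grid")
    j = int(hits[0])
    E = ensemble.E[:, j]
    M = ensemble.M[:, j]
    N = E + M
    alive = N > 0
    if not np.any(alive):
        raise DomainError(f"all replicates extinct at t={t}; fraction distribution empty")
    fractions = M[alive] / N[alive]
    return FractionDistribution(
        t=float(ensemble.t_grid[j]),
        fractions=fractions.astype(float),
        n_extinct=int(np.sum(~alive)),
    )
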