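"""Seeded in-silico experiments with known ground truth.

Bundles the simulator into complete multi-condition experiment designs that
produce exactly the CSV/series formats the estimation module consumes.
Ground truth is written to a separate file so analysis code cannot silently
read it.  No measurement-noise layer is applied by default — demographic
stochasticity *is* the noise model — but optional binomial subsampling of
counts is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from phenoswitch.errors import DomainError
from phenoswitch.estimate import MomentTimeSeries, series_from_counts
from phenoswitch.model import InitialComposition, RateParameters
from phenoswitch.simulate import EnsembleResult, simulate_ensemble

__all__ = ["Condition", "ExperimentDesign", "GeneratedExperiment",
           "generate_experiment", "default_fixture"]


@dataclass(frozen=True)
class Condition:
    """One designed initial condition with a unique label."""

    label: str
    init: InitialComposition


@dataclass(frozen=True)
class ExperimentDesign:
    """A complete replicated experiment with known ground-truth rates."""

    phase: str  # "drug" | "growth"
    conditions: tuple
    times: tuple
    n_replicates: int
    master_seed: int
    truth: RateParameters
    subsample: float | None = None  # optional binomial detection probability

    def __post_init__(self):
        if self.phase not in ("drug", "growth"):
            raise DomainError(f"unknown phase {self.phase!r}")
        times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("times must be strictly increasing")
        if self.n_replicates < 2:
            raise DomainError("need >= 2 replicates")
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise DomainError("condition labels must be unique")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "times", times)

    @property
    def effective_truth(self) -> RateParameters:
        """Rates actually simulated (drug phase forces the birth rates to 0)."""
        return self.truth.without_births() if self.phase == "drug" else self.truth


@dataclass
class GeneratedExperiment:
    """Raw counts, per-condition moment series, ensembles, and ground truth."""

    design: ExperimentDesign
    counts: pd.DataFrame  # condition, sample_id, time, E, M, N
    series: dict  # label -> MomentTimeSeries
    ensembles: dict  # label -> EnsembleResult

    def truth_dict(self) -> dict:
        return {
            "phase": self.design.phase,
            "rates": self.design.effective_truth.to_dict(),
            "conditions": {
                c.label: c.init.to_dict() for c in self.design.conditions
            },
            "times": list(self.design.times),
            "n_replicates": self.design.n_replicates,
            "master_seed": self.design.master_seed,
        }

    def write(self, counts_path, truth_path=None) -> None:
        self.counts.to_csv(counts_path, index=False)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump(self.truth_dict(), fh, indent=2)


def _grid_with_zero(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    return times if times[0] == 0.0 else np.concatenate([[0.0], times])


def generate_experiment(design: ExperimentDesign) -> GeneratedExperiment:
    """Simulate every condition of a design; bit-reproducible from the seed.

    Per-condition master seeds are spawned from the design seed with
    ``SeedSequence(master_seed).spawn`` in condition order, so adding a
    condition at the end never changes earlier conditions.
    """
    params = design.effective_truth
    grid = _grid_with_zero(design.times)
    children = np.random.SeedSequence(design.master_seed).spawn(
        2 * len(design.conditions)
    )
    frames = []
    series: dict[str, MomentTimeSeries] = {}
    ensembles: dict[str, EnsembleResult] = {}
    for i, cond in enumerate(design.conditions):
        ens = simulate_ensemble(
            params, cond.init, grid, design.n_replicates,
            seed=children[2 * i].generate_state(1)[0],
        )
        E, M = ens.E, ens.M
        if design.subsample is not None:
            rng = np.random.default_rng(children[2 * i + 1])
            E = rng.binomial(E, design.subsample)
            M = rng.binomial(M, design.subsample)
        df = pd.DataFrame(
            {
                "condition": cond.label,
                "sample_id": np.repeat(np.arange(design.n_replicates), grid.size),
                "time": np.tile(grid, design.n_replicates),
                "E": E.ravel(),
                "M": M.ravel(),
            }
        )
        df["N"] = df["E"] + df["M"]
        frames.append(df)
        series[cond.label] = series_from_counts(
            df, N0=cond.init.N0, label=cond.label
        )
        ensembles[cond.label] = replace(ens, E=E, M=M) if design.subsample else ens
    return GeneratedExperiment(
        design=design,
        counts=pd.concat(frames, ignore_index=True),
        series=series,
        ensembles=ensembles,
    )


# Default simulation-study fixture: growth design with per-phenotype rates
# k_E=0.2, k_M=0.1, mu_E=0.3, mu_M=0.15, switching ratio k_EM/k_ME set by
# fixing k_ME=0.1 (package convention; only the ratio is canonical), started
# from 200 sensitive cells, observed at t = 0.1, 1, 10, 20.
FIXTURE_RATES = dict(k_E=0.2, k_M=0.1, mu_E=0.3, mu_M=0.15)
FIXTURE_TIMES = (0.1, 1.0, 10.0, 20.0)
FIXTURE_E0 = 200


def default_fixture(
    switch_ratio: float = 1.0,
    *,
    phase: str = "growth",
    n_replicates: int = 10_000,
    master_seed: int = 20_200_615,
    k_ME: float = 0.1,
) -> ExperimentDesign:
    """The canonical simulation-study design with known ground truth.

    ``switch_ratio`` is ``k_EM / k_ME`` (0.1, 1, or 10 in the headline
    study); ``k_ME`` is fixed at 0.1 by package convention.  The growth
    design starts every replicate from 200 sensitive cells; the drug-phase
    companion keeps the same death/switching rates, suppresses births, and
    adds all-tolerant and Beta(2, 5)-mixed conditions for the estimation
    protocol.
    """
    truth = RateParameters(k_EM=switch_ratio * k_ME, k_ME=k_ME, **FIXTURE_RATES)
    if phase == "growth":
        conditions = (
            Condition("E0-only", InitialComposition(N0=FIXTURE_E0, p0=0.0, mode="deterministic")),
            Condition("M0-only", InitialComposition(N0=FIXTURE_E0, p0=1.0, mode="deterministic")),
        )
    else:
        conditions = (
            Condition("p0=0", InitialComposition(N0=FIXTURE_E0, p0=0.0)),
            Condition("p0=1", InitialComposition(N0=FIXTURE_E0, p0=1.0)),
            Condition("mixed", InitialComposition(N0=FIXTURE_E0, p0=("beta", 2.0, 5.0))),
        )
    return ExperimentDesign(
        phase=phase,
        conditions=conditions,
        times=FIXTURE_TIMES,
        n_replicates=n_replicates,
        master_seed=master_seed,
        truth=truth,
    )
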