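"""Generation loop: selection, within-host phases, immigration, trajectories.

Each host generation runs, in this fixed order:

1. within-host phase — ``generation_ratio - 1`` symbiont generations of
   growth-rate competition inside hosts, each followed by trickle
   immigration at rate ``m``;
2. simultaneous host and symbiont selection from the post-within-phase
   state: between-host symbiont selection (colonisation fitness) followed
   by immigration at rate ``M``, and host selection on the symbiont
   distribution the hosts carried during their lifetime;
3. record.

Host fitness is evaluated against the symbionts a host actually hosted
(the state after the within-host phase), not against the next generation's
colonists; likewise symbiont colonisation fitness sees the current host
generation.  This simultaneous update is what lets cooperation bootstrap at
generation ratio 1 — a sequential update in which hosts are scored against
the already-reselected symbiont pool under-counts the feedback and loses
the close race between rising host investment and declining symbiont
cooperation.

With ``generation_ratio = 1`` step 1 is a no-op and the model reduces to the
pure between-host model.  Selection is replicator reweighting on the trait
grid: frequencies are multiplied by max(fitness, 0) and renormalized.  There
is no mutation operator; evolution acts on the standing discretized
variation plus immigration, and host-side variation is never replenished.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .model_core import (
    HostPopulation,
    ModelParams,
    SymbiontPopulation,
    host_fitness_matrix,
    mean_trait_after_control_vector,
    symbiont_fitness_between_vector,
    symbiont_fitness_within_vector,
)

__all__ = [
    "EnvironmentalPool",
    "SimulationTrajectory",
    "truncated_normal_pmf",
    "init_host_population",
    "init_symbiont_population",
    "default_pool",
    "selection_step_hosts",
    "selection_step_symbionts",
    "apply_migration",
    "within_host_phase",
    "run_simulation",
]

CONVERGENCE_L1 = 1e-10


class ExtinctionError(RuntimeError):
    """All selection weights are zero: the population has no viable type."""


@dataclass(frozen=True)
class EnvironmentalPool:
    """Fixed source population of (largely uncooperative) immigrant microbes."""

    density: np.ndarray

    def mean_b(self, params: ModelParams) -> float:
        return float(self.density @ params.b_grid.values)


@dataclass
class SimulationTrajectory:
    """Per-host-generation record of a run; index 0 is the initial state."""

    params: ModelParams
    mean_a: list[float] = field(default_factory=list)
    mean_c: list[float] = field(default_factory=list)
    mean_b: list[float] = field(default_factory=list)
    mean_b_after_control: list[float] = field(default_factory=list)
    host_densities: list[np.ndarray] | None = None
    symbiont_densities: list[np.ndarray] | None = None
    final_host: HostPopulation | None = None
    final_symbiont: SymbiontPopulation | None = None
    converged_at: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return len(self.mean_a)

    def record(self, H: HostPopulation, S: SymbiontPopulation) -> None:
        p = self.params
        self.mean_a.append(H.mean_a(p.a_grid))
        self.mean_c.append(H.mean_c(p.c_grid))
        self.mean_b.append(S.mean_b(p.b_grid))
        # population-level mean cooperation after control, averaged over the
        # host control marginal
        bbar_c = mean_trait_after_control_vector(S.density, p)
        self.mean_b_after_control.append(float(bbar_c @ H.control_marginal()))
        if self.host_densities is not None:
            self.host_densities.append(H.density.copy())
        if self.symbiont_densities is not None:
            self.symbiont_densities.append(S.density.copy())

    def to_frame(self):
        """Means per generation as a pandas DataFrame."""
        import pandas as pd

        data = {
            "generation": np.arange(self.n_generations),
            "mean_a": self.mean_a,
            "mean_c": self.mean_c,
            "mean_b": self.mean_b,
            "mean_b_after_control": self.mean_b_after_control,
        }
        for key, vals in self.extra.items():
            if isinstance(vals, list) and len(vals) == self.n_generations:
                data[key] = vals
        return pd.DataFrame(data)


def truncated_normal_pmf(
    grid: np.ndarray, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Discretize a truncated normal onto grid points.

    Each grid point receives the truncated-normal density evaluated at the
    point; the vector is then normalized to sum to one (point-mass
    convention, no quadrature weights).
    """
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dens = stats.truncnorm.pdf(grid, a, b, loc=mean, scale=sd)
    return dens / dens.sum()


def init_host_population(params: ModelParams) -> HostPopulation:
    """Initial H(a, c): product of discretized truncated normals.

    Cooperation: mean 0, SD 0.5 on [0, 1].  Control: mean 0, SD 1 on
    [0, c_max] — wide enough that some pre-existing variation in control is
    present, without which cooperation collapses before control can act.
    With control disabled all control mass sits at c = 0.
    """
    a_pmf = truncated_normal_pmf(params.a_grid.values, 0.0, 0.5, 0.0, 1.0)
    if params.control_enabled:
        c_pmf = truncated_normal_pmf(
            params.c_grid.values, 0.0, 1.0, 0.0, params.c_max
        )
    else:
        c_pmf = np.zeros(params.n_grid)
        c_pmf[0] = 1.0
    return HostPopulation(np.outer(a_pmf, c_pmf))


def init_symbiont_population(params: ModelParams) -> SymbiontPopulation:
    """Initial S(b): truncated normal, mean 0, SD 0.5 on [0, 1]."""
    return SymbiontPopulation(
        truncated_normal_pmf(params.b_grid.values, 0.0, 0.5, 0.0, 1.0)
    )


def default_pool(params: ModelParams) -> EnvironmentalPool:
    """Environmental pool: the initial symbiont distribution.

    Largely uncooperative but with the small baseline of cooperation the
    truncated normal leaves above zero.
    """
    return EnvironmentalPool(init_symbiont_population(params).density)


def _reweight(density: np.ndarray, fitness: np.ndarray, what: str) -> np.ndarray:
    w = np.maximum(fitness, 0.0)
    new = density * w
    total = new.sum()
    if total <= 0.0:
        raise ExtinctionError(f"all {what} selection weights are zero")
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(f"non-finite {what} fitness encountered")
    return new / total


def selection_step_hosts(
    H: HostPopulation, S: SymbiontPopulation, params: ModelParams
) -> HostPopulation:
    """One generation of host selection: H'(a,c) ∝ H(a,c) max(W_a, 0)."""
    W = host_fitness_matrix(S.density, params)
    return HostPopulation(_reweight(H.density, W, "host"))


def selection_step_symbionts(
    S: SymbiontPopulation,
    H: HostPopulation,
    params: ModelParams,
    phase: str = "between",
) -> SymbiontPopulation:
    """One symbiont selection step, between- or within-host fitness."""
    if phase == "between":
        W = symbiont_fitness_between_vector(H.density, S.density, params)
    elif phase == "within":
        W = symbiont_fitness_within_vector(H.density, S.density, params)
    else:
        raise ValueError(f"phase must be 'between' or 'within', got {phase!r}")
    return SymbiontPopulation(_reweight(S.density, W, "symbiont"))


def apply_migration(
    S: SymbiontPopulation, pool: EnvironmentalPool, rate: float
) -> SymbiontPopulation:
    """Mix immigrants in: S' = (1 - rate) S + rate * pool."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"migration rate {rate} outside [0, 1]")
    return SymbiontPopulation((1.0 - rate) * S.density + rate * pool.density)


def within_host_phase(
    S: SymbiontPopulation,
    H: HostPopulation,
    params: ModelParams,
    pool: EnvironmentalPool,
) -> SymbiontPopulation:
    """(generation_ratio - 1) rounds of within-host selection + immigration m.

    A ratio of 1 is the identity, so the pure between-host model is
    recovered exactly.
    """
    for _ in range(params.generation_ratio - 1):
        S = selection_step_symbionts(S, H, params, phase="within")
        S = apply_migration(S, pool, params.m)
    return S


def run_simulation(
    params: ModelParams,
    pool: EnvironmentalPool | None = None,
    *,
    record_densities: bool = False,
    progress: Callable[[int], None] | None = None,
) -> SimulationTrajectory:
    """Run the deterministic model for n_host_generations.

    Stops early when the L1 change of both the host and symbiont densities
    over one host generation falls below 1e-10.  The run is fully
    deterministic: identical parameters give bit-identical trajectories.
    """
    if pool is None:
        pool = default_pool(params)
    H = init_host_population(params)
    S = init_symbiont_population(params)
    traj = SimulationTrajectory(params=params)
    if record_densities:
        traj.host_densities = []
        traj.symbiont_densities = []
    traj.record(H, S)
    for gen in range(1, params.n_host_generations + 1):
        H_prev, S_prev = H.density, S.density
        S = within_host_phase(S, H, params, pool)
        # simultaneous update: host fitness sees the symbionts of this
        # generation, symbiont colonisation fitness sees this generation's
        # hosts
        H_next = selection_step_hosts(H, S, params)
        S = selection_step_symbionts(S, H, params, phase="between")
        S = apply_migration(S, pool, params.M)
        H = H_next
        traj.record(H, S)
        if progress is not None:
            progress(gen)
        dH = np.abs(H.density - H_prev).sum()
        dS = np.abs(S.density - S_prev).sum()
        if dH < CONVERGENCE_L1 and dS < CONVERGENCE_L1:
            traj.converged_at = gen
            break
    traj.final_host = H
    traj.final_symbiont = S
    return traj
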