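"""Trait-cooperation decoupling: symbionts can escape host control.

Host control monitors an expressed trait ``B`` (flagella, a surface antigen),
not cooperation itself.  Symbionts carry a linkage trait ``gamma`` in [0, 1]
setting how much of the expressed trait translates into realized
cooperation::

    b = gamma * B

With gamma pinned at 1 the base model is recovered exactly.  When gamma is
free to evolve, selection favours genotypes that keep expressing the
monitored trait (high B, rewarded by control) while cooperating less
(low gamma), and both cooperation and host control collapse.  The control
weight q is evaluated with the *expressed* trait B in its exponent and in
its population denominator; cooperation cost and feedback use b = gamma*B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evolution import (
    EnvironmentalPool,
    ExtinctionError,
    SimulationTrajectory,
    _reweight,
    default_pool,
    init_host_population,
)
from .model_core import (
    HostPopulation,
    ModelParams,
    TraitGrid,
    _check_density,
    host_fitness_matrix,
    mean_trait_after_control_vector,
    symbiont_fitness_between_vector,
    symbiont_fitness_within_vector,
)
from .evolution import truncated_normal_pmf

__all__ = [
    "LinkedSymbiontPopulation",
    "EscapePhase",
    "effective_cooperation",
    "init_linked_population",
    "default_linked_pool",
    "run_escape_simulation",
]


def effective_cooperation(B, gamma):
    """Realized cooperation b = gamma * B."""
    B = np.asarray(B, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(B < 0) or np.any(B > 1) or np.any(gamma < 0) or np.any(gamma > 1):
        raise ValueError("B and gamma must lie in [0, 1]")
    out = gamma * B
    return float(out) if out.ndim == 0 else out


@dataclass
class LinkedSymbiontPopulation:
    """Joint density over (B-grid x gamma-grid)."""

    density: np.ndarray  # shape (n_B, n_gamma)

    def __post_init__(self) -> None:
        self.density = _check_density(self.density, "linked symbiont density")
        if self.density.ndim != 2:
            raise ValueError("linked density must be 2-D over (B, gamma)")

    def b_marginal(self) -> np.ndarray:
        return self.density.sum(axis=1)

    def gamma_marginal(self) -> np.ndarray:
        return self.density.sum(axis=0)

    def mean_B(self, grid: TraitGrid) -> float:
        return float(self.b_marginal() @ grid.values)

    def mean_gamma(self, grid: TraitGrid) -> float:
        return float(self.gamma_marginal() @ grid.values)

    def mean_b(self, grid: TraitGrid) -> float:
        b_eff = np.outer(grid.values, grid.values)  # gamma * B
        return float((self.density * b_eff).sum())

    def project_fixed_gamma(self) -> "LinkedSymbiontPopulation":
        """Move all mass to gamma = 1, preserving the B-marginal."""
        new = np.zeros_like(self.density)
        new[:, -1] = self.b_marginal()
        return LinkedSymbiontPopulation(new)


@dataclass(frozen=True)
class EscapePhase:
    """A contiguous block of host generations with gamma fixed or free."""

    n_generations: int
    gamma_mode: str  # "fixed" (pinned at 1) or "free"

    def __post_init__(self) -> None:
        if self.gamma_mode not in ("fixed", "free"):
            raise ValueError("gamma_mode must be 'fixed' or 'free'")
        if self.n_generations < 0:
            raise ValueError("phase length must be >= 0")


def _gamma_pmf(params: ModelParams) -> np.ndarray:
    # immigrant/initial linkage: largely unlinked (environmental microbes
    # express the trait for their own reasons, not as part of the mutualism),
    # same truncated-normal shape as the cooperation traits
    return truncated_normal_pmf(params.b_grid.values, 0.0, 0.5, 0.0, 1.0)


def init_linked_population(params: ModelParams) -> LinkedSymbiontPopulation:
    """Initial joint density: independent truncated normals on B and gamma.

    The gamma axis carries standing variation; runs that start in a
    "fixed" phase immediately project it onto gamma = 1 (preserving the
    B-marginal), recovering the base model's initial condition exactly.
    """
    B_pmf = truncated_normal_pmf(params.b_grid.values, 0.0, 0.5, 0.0, 1.0)
    return LinkedSymbiontPopulation(np.outer(B_pmf, _gamma_pmf(params)))


def default_linked_pool(params: ModelParams) -> EnvironmentalPool:
    """Immigrants: base pool on B crossed with the unlinked gamma pmf.

    Replicator dynamics cannot create mass where there is none, so the
    variation in the trait-cooperation link that "free" phases select on
    enters through immigration; a pool concentrated at gamma = 1 would
    leave the link unable to evolve at all.  In "fixed" phases the
    per-generation projection onto gamma = 1 makes the B-marginal dynamics
    identical to the base model whatever the pool's gamma distribution.
    """
    base = default_pool(params).density
    return EnvironmentalPool(np.outer(base, _gamma_pmf(params)))


def _linked_axes(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(b_expressed, b_effective) matrices on the (B, gamma) grid."""
    B = params.b_grid.values
    gamma = params.b_grid.values  # gamma shares the [0, 1] grid
    b_expressed = np.broadcast_to(B[:, None], (len(B), len(gamma))).copy()
    b_effective = np.outer(B, gamma)
    return b_expressed, b_effective


def _linked_selection(
    S: LinkedSymbiontPopulation,
    H: HostPopulation,
    params: ModelParams,
    phase: str,
) -> LinkedSymbiontPopulation:
    b_expressed, b_effective = _linked_axes(params)
    if phase == "between":
        W = symbiont_fitness_between_vector(
            H.density, S.density, params,
            b_effective=b_effective, b_expressed=b_expressed,
        )
    else:
        W = symbiont_fitness_within_vector(
            H.density, S.density, params,
            b_effective=b_effective, b_expressed=b_expressed,
        )
    return LinkedSymbiontPopulation(_reweight(S.density, W, "symbiont"))


def _linked_migration(
    S: LinkedSymbiontPopulation, pool: EnvironmentalPool, rate: float
) -> LinkedSymbiontPopulation:
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"migration rate {rate} outside [0, 1]")
    return LinkedSymbiontPopulation(
        (1.0 - rate) * S.density + rate * pool.density
    )


def _linked_host_fitness(
    S: LinkedSymbiontPopulation, params: ModelParams
) -> np.ndarray:
    b_expressed, b_effective = _linked_axes(params)
    bbar_c = mean_trait_after_control_vector(
        S.density, params,
        b_effective=b_effective, b_expressed=b_expressed,
    )
    return host_fitness_matrix(None, params, bbar_c=bbar_c)


def run_escape_simulation(
    params: ModelParams,
    schedule: list[EscapePhase | tuple[int, str]],
    pool: EnvironmentalPool | None = None,
    *,
    record_densities: bool = False,
) -> SimulationTrajectory:
    """Run the linked model through an ordered schedule of gamma phases.

    In "fixed" phases the joint density is projected onto gamma = 1 each
    generation (preserving B-marginals); in "free" phases the full
    (B, gamma) grid evolves under selection and immigration.  Records mean
    b, mean B, mean gamma and mean c per host generation.
    """
    schedule = [
        p if isinstance(p, EscapePhase) else EscapePhase(*p) for p in schedule
    ]
    if pool is None:
        pool = default_linked_pool(params)
    H = init_host_population(params)
    S = init_linked_population(params)

    grid = params.b_grid
    traj = SimulationTrajectory(params=params)
    traj.extra["mean_B"] = []
    traj.extra["mean_gamma"] = []
    traj.extra["gamma_mode"] = []
    if record_densities:
        traj.host_densities = []
        traj.symbiont_densities = []

    def record(mode: str) -> None:
        traj.mean_a.append(H.mean_a(params.a_grid))
        traj.mean_c.append(H.mean_c(params.c_grid))
        traj.mean_b.append(S.mean_b(grid))
        b_expressed, b_effective = _linked_axes(params)
        bbar_c = mean_trait_after_control_vector(
            S.density, params,
            b_effective=b_effective, b_expressed=b_expressed,
        )
        traj.mean_b_after_control.append(float(bbar_c @ H.control_marginal()))
        traj.extra["mean_B"].append(S.mean_B(grid))
        traj.extra["mean_gamma"].append(S.mean_gamma(grid))
        traj.extra["gamma_mode"].append(mode)
        if traj.host_densities is not None:
            traj.host_densities.append(H.density.copy())
        if traj.symbiont_densities is not None:
            traj.symbiont_densities.append(S.density.copy())

    if schedule and schedule[0].gamma_mode == "fixed":
        S = S.project_fixed_gamma()
    record(schedule[0].gamma_mode if schedule else "fixed")
    for block in schedule:
        fixed = block.gamma_mode == "fixed"
        if fixed:
            S = S.project_fixed_gamma()
        for _ in range(block.n_generations):
            # within-host phase
            for _ in range(params.generation_ratio - 1):
                S = _linked_selection(S, H, params, "within")
                S = _linked_migration(S, pool, params.m)
                if fixed:
                    S = S.project_fixed_gamma()
            # simultaneous update: host fitness sees this generation's
            # symbionts, symbiont colonisation fitness this generation's hosts
            W_a = _linked_host_fitness(S, params)
            H_next = HostPopulation(_reweight(H.density, W_a, "host"))
            S = _linked_selection(S, H, params, "between")
            S = _linked_migration(S, pool, params.M)
            if fixed:
                S = S.project_fixed_gamma()
            H = H_next
            record(block.gamma_mode)
    traj.final_host = H
    traj.final_symbiont = None
    traj.extra["final_linked_symbiont"] = S
    return traj
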