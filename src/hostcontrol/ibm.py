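"""Individual-based (stochastic) version of the model, with pathogens.

Hosts and microbes are finite populations of individuals whose traits sit on
the same grids as the deterministic model, so the IBM is its exact
finite-population counterpart: every selection step replaces deterministic
reweighting with multinomial resampling proportional to the same fitness
weights.  On top of the resident symbionts the IBM admits an influx of rare
pathogens — microbes that fully express the monitored trait (B = 1) while
not cooperating (b = 0) and that harm hosts far beyond a mere lack of
cooperation.  The harm is the pathogenicity factor::

    p_f = exp(v p c / c_max) * exp(-v p)

with ``p`` the within-host pathogen proportion and ``v`` the virulence;
``p_f`` multiplies host fitness, equals 1 when p = 0 or c = c_max, and
falls to exp(-v p) for an uncontrolled host.  The exponent means even a few
pathogens in a host are very costly at high v.

Each host generation: (generation_ratio - 1) within-host rounds of
multinomial resampling on within-host fitness (with trickle immigration m),
then pathogen influx, then host reproduction proportional to
max(W_a, 0) * p_f, then colonisation of offspring hosts by multinomial
draws from the parental microbe pool weighted by between-host fitness and
mixed with environmental immigrants at rate M.  Host fitness is scored
against the pooled symbiont distribution the hosts carried this generation,
mirroring the simultaneous update of the deterministic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evolution import (
    EnvironmentalPool,
    ExtinctionError,
    SimulationTrajectory,
    default_pool,
    truncated_normal_pmf,
)
from .model_core import (
    ModelParams,
    benefit_transform,
    mean_trait_after_control_vector,
    symbiont_fitness_between_vector,
)

__all__ = [
    "IBMConfig",
    "IBMState",
    "pathogenicity_factor",
    "genotype_tables",
    "ibm_init",
    "ibm_host_generation",
    "run_ibm",
]


@dataclass(frozen=True)
class IBMConfig:
    """Configuration of the individual-based model.

    Defaults mirror the full-scale experiment (1e4 hosts x 1e3 microbes per
    host = 1e7 microbes); tests and routine exploration use scaled-down
    populations via ``with_()``-style replacement.
    """

    params: ModelParams = field(default_factory=ModelParams)
    n_hosts: int = 10_000
    microbes_per_host: int = 1000
    virulence: float = 50.0  # v: fitness cost steepness of pathogen carriage
    pathogen_influx: float = 0.0  # fraction of microbes replaced per host gen
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_hosts < 1 or self.microbes_per_host < 1:
            raise ValueError("population sizes must be >= 1")
        if self.virulence < 0:
            raise ValueError("virulence must be >= 0")
        if not 0.0 <= self.pathogen_influx <= 1.0:
            raise ValueError("pathogen_influx must lie in [0, 1]")

    @property
    def total_microbes(self) -> int:
        return self.n_hosts * self.microbes_per_host

    def with_(self, **updates) -> "IBMConfig":
        return replace(self, **updates)


def pathogenicity_factor(p, c, config: IBMConfig):
    """Multiplicative host-fitness penalty p_f from pathogen carriage.

    ``p_f = exp(v p c/c_max) * exp(-v p)`` in (0, 1]; equals 1 when p = 0
    (no pathogens) or c = c_max (full control nullifies the harm).
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pathogen proportion must lie in [0, 1]")
    v = config.virulence
    c_max = config.params.c_max
    out = np.exp(v * p * (c / c_max)) * np.exp(-v * p)
    return float(out) if out.ndim == 0 else out


def genotype_tables(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(cooperation b_g, control-relevant expression B_g) per microbe genotype.

    Genotypes 0..n_grid-1 are resident symbionts with B = b on the b-grid;
    the final genotype is the pathogen.  Pathogens do not cooperate (b = 0)
    and are subject to host control exactly like non-cooperative symbionts
    (B = 0 in the control weighting): control suppresses them within hosts
    while the pathogenicity factor p_f punishes hosts that fail to do so.
    What distinguishes a pathogen from a mere defector is the p_f harm, not
    its standing under control.
    """
    b = params.b_grid.values
    b_vals = np.append(b, 0.0)
    B_vals = np.append(b, 0.0)
    return b_vals, B_vals


@dataclass
class IBMState:
    """Finite-population state: per-host traits and per-host genotype counts.

    Host traits and microbe genotypes are stored as grid indices; the
    per-individual trait arrays are exposed as views (``host_a``,
    ``microbe_b`` etc.).  ``counts[i, g]`` is the number of microbes of
    genotype g carried by host i; every microbe belongs to exactly one host
    and row sums equal microbes_per_host.
    """

    host_a_idx: np.ndarray  # (n_hosts,) index into the a-grid
    host_c_idx: np.ndarray  # (n_hosts,) index into the c-grid
    counts: np.ndarray  # (n_hosts, n_genotypes)
    params: ModelParams
    generation: int = 0

    # per-individual views ------------------------------------------------
    @property
    def host_a(self) -> np.ndarray:
        return self.params.a_grid.values[self.host_a_idx]

    @property
    def host_c(self) -> np.ndarray:
        return self.params.c_grid.values[self.host_c_idx]

    @property
    def pathogen_index(self) -> int:
        return self.counts.shape[1] - 1

    def microbe_genotypes(self) -> np.ndarray:
        """Per-individual genotype index (grouped by host)."""
        return np.repeat(
            np.tile(np.arange(self.counts.shape[1]), self.counts.shape[0]),
            self.counts.reshape(-1),
        )

    def microbe_host_assignment(self) -> np.ndarray:
        """Per-individual host index, aligned with microbe_genotypes()."""
        return np.repeat(
            np.arange(self.counts.shape[0]), self.counts.sum(axis=1)
        )

    def microbe_b(self) -> np.ndarray:
        b_vals, _ = genotype_tables(self.params)
        return b_vals[self.microbe_genotypes()]

    def pathogen_flags(self) -> np.ndarray:
        return self.microbe_genotypes() == self.pathogen_index

    def pathogen_proportions(self) -> np.ndarray:
        """Within-host pathogen proportion p, one entry per host."""
        return self.counts[:, -1] / self.counts.sum(axis=1)

    # summary means --------------------------------------------------------
    def mean_a(self) -> float:
        return float(self.host_a.mean())

    def mean_c(self) -> float:
        return float(self.host_c.mean())

    def mean_b(self) -> float:
        b_vals, _ = genotype_tables(self.params)
        tot = self.counts.sum()
        return float((self.counts.sum(axis=0) @ b_vals) / tot)

    def pathogen_prevalence(self) -> float:
        return float(self.counts[:, -1].sum() / self.counts.sum())


def _extended_pool(pool: EnvironmentalPool) -> np.ndarray:
    """Environmental pool pmf over the extended genotype list (no pathogens)."""
    return np.append(pool.density, 0.0)


def ibm_init(config: IBMConfig, rng: np.random.Generator | None = None) -> IBMState:
    """Draw the initial finite populations.

    Host and microbe traits are sampled from the discretized truncated
    normals of the deterministic model (cooperation: mean 0, SD 0.5;
    control: mean 0, SD 1, or pinned to 0 when control is disabled); each
    host receives exactly microbes_per_host microbes; no pathogens at
    initialization (they arrive by influx only).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.params
    n = params.n_grid
    a_pmf = truncated_normal_pmf(params.a_grid.values, 0.0, 0.5, 0.0, 1.0)
    host_a_idx = rng.choice(n, size=config.n_hosts, p=a_pmf)
    if params.control_enabled:
        c_pmf = truncated_normal_pmf(params.c_grid.values, 0.0, 1.0, 0.0, params.c_max)
        host_c_idx = rng.choice(n, size=config.n_hosts, p=c_pmf)
    else:
        host_c_idx = np.zeros(config.n_hosts, dtype=np.int64)
    b_pmf = truncated_normal_pmf(params.b_grid.values, 0.0, 0.5, 0.0, 1.0)
    geno_pmf = np.append(b_pmf, 0.0)  # no pathogens initially
    counts = rng.multinomial(config.microbes_per_host, geno_pmf, size=config.n_hosts)
    return IBMState(host_a_idx, host_c_idx, counts, params)


def _within_host_fitness(state: IBMState, config: IBMConfig) -> np.ndarray:
    """Within-host fitness W[i, g] = (1 - b_g) + q_i(g).

    q uses the focal host's control level and the host's *own* microbe
    distribution in the competition denominator (pure local competition).
    """
    params = config.params
    b_vals, B_vals = genotype_tables(params)
    c = state.host_c  # (n_hosts,)
    freq = state.counts / state.counts.sum(axis=1, keepdims=True)
    expo = np.outer(c, B_vals)  # (n_hosts, G)
    denom = (np.exp((1.0 - params.R) * expo) * freq).sum(axis=1)
    q = np.exp(expo) / denom[:, None] * np.exp(-params.f * c)[:, None]
    return (1.0 - b_vals)[None, :] + q


def _resample_within(counts, W, mph, rng) -> np.ndarray:
    pv = counts * np.maximum(W, 0.0)
    tot = pv.sum(axis=1)
    if np.any(tot <= 0.0):
        raise ExtinctionError("a host's microbes all have zero fitness")
    return rng.multinomial(mph, pv / tot[:, None])


def _replace_random_microbes(counts, rate, replacement_pmf, rng) -> np.ndarray:
    """Each microbe is independently replaced with prob `rate` by a draw
    from `replacement_pmf` (used for trickle immigration and pathogen influx)."""
    if rate <= 0.0:
        return counts
    mph = counts.sum(axis=1)
    n_replace = rng.binomial(mph, rate)
    if not n_replace.any():
        return counts
    counts = counts.copy()
    for i in np.nonzero(n_replace)[0]:
        removed = rng.multivariate_hypergeometric(counts[i], n_replace[i])
        counts[i] -= removed
        counts[i] += rng.multinomial(n_replace[i], replacement_pmf)
    return counts


def _empirical_host_density(state: IBMState) -> np.ndarray:
    n = state.params.n_grid
    H = np.zeros((n, n))
    np.add.at(H, (state.host_a_idx, state.host_c_idx), 1.0)
    return H / len(state.host_a_idx)


def ibm_host_generation(
    state: IBMState,
    config: IBMConfig,
    rng: np.random.Generator,
    pool: EnvironmentalPool | None = None,
) -> IBMState:
    """Advance the IBM by one host generation (see module docstring)."""
    params = config.params
    if pool is None:
        pool = default_pool(params)
    pool_ext = _extended_pool(pool)
    b_vals, B_vals = genotype_tables(params)
    mph = config.microbes_per_host
    counts = state.counts

    # 1. within-host symbiont generations + trickle immigration
    work = IBMState(state.host_a_idx, state.host_c_idx, counts, params)
    for _ in range(params.generation_ratio - 1):
        W = _within_host_fitness(work, config)
        work.counts = _resample_within(work.counts, W, mph, rng)
        work.counts = _replace_random_microbes(work.counts, params.m, pool_ext, rng)
    # pathogen influx once per host generation
    work.counts = _replace_random_microbes(
        work.counts, config.pathogen_influx,
        np.eye(len(b_vals))[-1], rng,
    )
    counts = work.counts

    # 2. colonisation distribution for the next microbe generation:
    # between-host fitness on the pooled empirical densities, then
    # environmental immigration at rate M
    S_emp = counts.sum(axis=0) / counts.sum()
    H_emp = _empirical_host_density(state)
    W_b = symbiont_fitness_between_vector(
        H_emp, S_emp, params, b_effective=b_vals, b_expressed=B_vals
    )
    w = np.maximum(W_b, 0.0) * S_emp
    if w.sum() <= 0.0:
        raise ExtinctionError("all microbe colonisation weights are zero")
    pcol = (1.0 - params.M) * (w / w.sum()) + params.M * pool_ext

    # 3. host reproduction: W_a is scored against the symbionts the hosts
    # carried this generation (the pooled post-within-phase distribution,
    # as in the deterministic engine's simultaneous update), times p_f
    bbar_c = mean_trait_after_control_vector(
        S_emp, params, b_effective=b_vals, b_expressed=B_vals
    )
    bbar_i = bbar_c[state.host_c_idx]
    benefit = benefit_transform(bbar_i, params.benefit_form)
    a_i, c_i = state.host_a, state.host_c
    W_a = (
        (1.0 - a_i)
        + params.x * a_i * params.y * benefit
        - params.g * c_i / params.c_max
    )
    p_i = counts[:, -1] / mph
    p_f = pathogenicity_factor(p_i, c_i, config)
    wh = np.maximum(W_a, 0.0) * p_f
    if wh.sum() <= 0.0:
        raise ExtinctionError("all host fitness weights are zero")
    parents = rng.choice(config.n_hosts, size=config.n_hosts, p=wh / wh.sum())

    # 4. offspring hosts are colonised by draws from the pooled parental
    # microbes (fitness-weighted, immigration-mixed)
    new_counts = rng.multinomial(mph, pcol, size=config.n_hosts)
    return IBMState(
        state.host_a_idx[parents],
        state.host_c_idx[parents],
        new_counts,
        params,
        generation=state.generation + 1,
    )


def run_ibm(
    config: IBMConfig,
    pool: EnvironmentalPool | None = None,
    n_generations: int | None = None,
) -> SimulationTrajectory:
    """Run the IBM and record per-host-generation summary means.

    Fully reproducible: the same config (including seed) gives identical
    trajectories.
    """
    params = config.params
    if pool is None:
        pool = default_pool(params)
    if n_generations is None:
        n_generations = params.n_host_generations
    rng = np.random.default_rng(config.seed)
    state = ibm_init(config, rng)
    traj = SimulationTrajectory(params=params)
    traj.extra["pathogen_prevalence"] = []
    traj.extra["seed"] = config.seed

    def record(st: IBMState) -> None:
        traj.mean_a.append(st.mean_a())
        traj.mean_c.append(st.mean_c())
        traj.mean_b.append(st.mean_b())
        b_vals, B_vals = genotype_tables(params)
        S_emp = st.counts.sum(axis=0) / st.counts.sum()
        bbar_c = mean_trait_after_control_vector(
            S_emp, params, b_effective=b_vals, b_expressed=B_vals
        )
        h_c = np.bincount(st.host_c_idx, minlength=params.n_grid) / len(st.host_c_idx)
        traj.mean_b_after_control.append(float(bbar_c @ h_c))
        traj.extra["pathogen_prevalence"].append(st.pathogen_prevalence())

    record(state)
    for _ in range(n_generations):
        state = ibm_host_generation(state, config, rng, pool)
        record(state)
    traj.extra["final_state"] = state
    return traj
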