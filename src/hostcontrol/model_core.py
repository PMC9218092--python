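"""Fitness and control equations of the host-microbiome cooperation model.

The model follows a focal symbiont species (or niche) interacting with a host
population.  Hosts carry two evolving traits: investment in cooperation
``a`` in [0, 1] and investment in a control mechanism ``c`` in [0, c_max]
that preferentially benefits more-cooperative symbionts.  Symbionts carry a
single cooperation trait ``b`` in [0, 1].  Populations are represented as
probability densities on evenly spaced trait grids (point masses at the grid
values), so every integral in the fitness equations is a probability-weighted
sum over grid points.

Host fitness::

    W_a = (1 - a) + x * p_a * beta(bbar(c)) - g * (c / c_max)

with partner-fidelity feedback ``p_a = a * y`` and ``beta`` an optional
benefit-transform applied to the post-control mean cooperation ``bbar(c)``
(identity for the linear form).

Host control reweights symbionts exponentially in their expressed trait::

    q(b, c) = exp(b c) / sum_b' exp((1 - R) b' c) S(b')  *  exp(-f c)

where ``R`` is symbiont relatedness (control cannot discriminate within a
clonal population, R = 1), and ``f`` is a blanket suppression cost paid by
all symbionts under control.

Symbiont fitness has a between-host form (colonisation of next-generation
hosts, carrying feedback benefits)::

    W_b = (1 - b) + y * sum_{a,c} H(a,c) q(b,c) p_b(c) a

with ``p_b(c) = R b x + (1 - R) bbar(c) x``, and a within-host form (pure
local competition on relative growth rate)::

    W_b = (1 - b) + sum_c q(b,c) h(c)

where ``h(c)`` is the marginal density of control among hosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

__all__ = [
    "BENEFIT_FORMS",
    "ModelParams",
    "TraitGrid",
    "HostPopulation",
    "SymbiontPopulation",
    "benefit_transform",
    "benefit_as_printed",
    "control_effect",
    "control_effect_matrix",
    "mean_trait_after_control",
    "host_feedback",
    "symbiont_feedback",
    "host_fitness",
    "host_fitness_matrix",
    "symbiont_fitness_between",
    "symbiont_fitness_between_vector",
    "symbiont_fitness_within",
    "symbiont_fitness_within_vector",
]

NORM_TOL = 1e-12

BenefitForm = Literal["linear", "diminishing", "accelerating", "sigmoidal"]
BENEFIT_FORMS = ("linear", "diminishing", "accelerating", "sigmoidal")


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for the deterministic trait-distribution model.

    Defaults are the headline regime of the model: benefit coefficients
    x = y = 2, relatedness R = 0.5, symbiont-side control cost f = 0.02,
    host-side control cost g = 0.1, immigration M = 0.05 per host generation
    and m = 1e-6 per symbiont generation.
    """

    x: float = 2.0  # benefit to hosts of receiving symbiont cooperation
    y: float = 2.0  # benefit to symbionts of receiving host cooperation
    R: float = 0.5  # symbiont relatedness in [0, 1]
    f: float = 0.02  # symbiont-side cost of host control
    g: float = 0.1  # host-side (direct) cost of control
    M: float = 0.05  # immigration fraction per host generation
    m: float = 1e-6  # immigration fraction per symbiont generation
    generation_ratio: int = 1  # symbiont generations per host generation
    c_max: float = 10.0  # upper bound of the control trait
    n_grid: int = 11  # grid points per trait axis
    benefit_form: str = "linear"
    n_host_generations: int = 200
    control_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"R must lie in [0, 1], got {self.R}")
        for name in ("M", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("f", "g"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.generation_ratio < 1:
            raise ValueError("generation_ratio must be an integer >= 1")
        if self.c_max <= 0.0:
            raise ValueError("c_max must be > 0")
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        if self.benefit_form not in BENEFIT_FORMS:
            raise ValueError(
                f"unknown benefit_form {self.benefit_form!r}; "
                f"expected one of {BENEFIT_FORMS}"
            )
        if self.n_host_generations < 1:
            raise ValueError("n_host_generations must be >= 1")

    # trait grids ---------------------------------------------------------
    @property
    def a_grid(self) -> "TraitGrid":
        return _grid_cache(0.0, 1.0, self.n_grid)

    @property
    def b_grid(self) -> "TraitGrid":
        return _grid_cache(0.0, 1.0, self.n_grid)

    @property
    def c_grid(self) -> "TraitGrid":
        return _grid_cache(0.0, self.c_max, self.n_grid)

    def with_(self, **updates) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class TraitGrid:
    """Evenly spaced, endpoint-inclusive support for a trait interval."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def linear(cls, lo: float, hi: float, n: int) -> "TraitGrid":
        return cls(np.linspace(lo, hi, n))

    def __len__(self) -> int:
        return len(self.values)


@lru_cache(maxsize=128)
def _grid_cache(lo: float, hi: float, n: int) -> TraitGrid:
    grid = TraitGrid.linear(lo, hi, n)
    grid.values.flags.writeable = False
    return grid


@lru_cache(maxsize=256)
def _exp_tables(
    b_bytes: bytes, n_b: int, c_bytes: bytes, n_c: int, R: float, f: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cached exponential tables for q: (e^{bc}, e^{(1-R)bc}, e^{-fc})."""
    b = np.frombuffer(b_bytes, dtype=float)
    c = np.frombuffer(c_bytes, dtype=float)
    bc = np.outer(b, c)
    tables = (np.exp(bc), np.exp((1.0 - R) * bc), np.exp(-f * c))
    for t in tables:
        t.flags.writeable = False
    return tables


def _check_density(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} is not normalized (sum = {p.sum()!r})")
    return p


@dataclass
class HostPopulation:
    """Probability density H(a, c) over the host cooperation x control grid."""

    density: np.ndarray  # shape (n_a, n_c)

    def __post_init__(self) -> None:
        self.density = _check_density(self.density, "host density")
        if self.density.ndim != 2:
            raise ValueError("host density must be a 2-D matrix over (a, c)")

    def mean_a(self, grid: TraitGrid) -> float:
        return float(self.density.sum(axis=1) @ grid.values)

    def mean_c(self, grid: TraitGrid) -> float:
        return float(self.density.sum(axis=0) @ grid.values)

    def control_marginal(self) -> np.ndarray:
        """Marginal density h(c) of the control trait."""
        return self.density.sum(axis=0)


@dataclass
class SymbiontPopulation:
    """Probability density S(b) over symbiont cooperation."""

    density: np.ndarray  # shape (n_b,)

    def __post_init__(self) -> None:
        self.density = _check_density(self.density, "symbiont density")
        if self.density.ndim != 1:
            raise ValueError("symbiont density must be a 1-D vector over b")

    def mean_b(self, grid: TraitGrid) -> float:
        return float(self.density @ grid.values)


# ---------------------------------------------------------------------------
# benefit transforms
# ---------------------------------------------------------------------------

def _diminishing(u: np.ndarray) -> np.ndarray:
    # saturating hyperbola anchored at (0,0) and (1,1); concave
    return u / (u + 0.3 * (1.0 - u))


def _accelerating(u: np.ndarray) -> np.ndarray:
    # mirror image of the diminishing curve; convex, same anchors
    return 1.0 - _diminishing(1.0 - u)


def _sigmoidal(u: np.ndarray) -> np.ndarray:
    # smoothstep: convex then concave, zero slope at both anchors
    return u * u * (3.0 - 2.0 * u)


_BENEFIT_FUNCS = {
    "linear": lambda u: u,
    "diminishing": _diminishing,
    "accelerating": _accelerating,
    "sigmoidal": _sigmoidal,
}


def benefit_transform(bbar, form: str = "linear"):
    """Map post-control mean cooperation onto the benefit felt by the host.

    All forms are anchored at (0, 0) and (1, 1): zero cooperation yields zero
    benefit and full cooperation yields the full benefit, with the shape in
    between set by ``form``.  ``linear`` is the identity.
    """
    if form not in _BENEFIT_FUNCS:
        raise ValueError(f"unknown benefit form {form!r}")
    u = np.asarray(bbar, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("mean cooperation must lie in [0, 1]")
    out = _BENEFIT_FUNCS[form](np.clip(u, 0.0, 1.0))
    return float(out) if np.isscalar(bbar) else out


def benefit_as_printed(bbar, form: str):
    """Literal textbook formulas for the non-linear benefit curves.

    Provided for inspection only: the 'diminishing' expression
    ``1 - (1-b)/(1-6b)`` has a pole at b = 1/6 and the 'sigmoidal' expression
    ``(1 + b/(1+b))**6`` exceeds 1, so these are *not* used as defaults
    (see :func:`benefit_transform`).
    """
    u = np.asarray(bbar, dtype=float)
    if form == "diminishing":
        out = 1.0 - (1.0 - u) / (1.0 - 6.0 * u)
    elif form == "accelerating":
        out = u / (u + 0.3 * (1.0 - u))
    elif form == "sigmoidal":
        out = (1.0 + u / (1.0 + u)) ** 6
    elif form == "linear":
        out = u
    else:
        raise ValueError(f"unknown benefit form {form!r}")
    return float(out) if np.isscalar(bbar) else out


# ---------------------------------------------------------------------------
# control and fitness
# ---------------------------------------------------------------------------

def _check_c(c: float, params: ModelParams) -> None:
    if not 0.0 <= c <= params.c_max * (1 + 1e-12):
        raise ValueError(f"control level {c} outside [0, {params.c_max}]")


def control_effect(
    b: float, c: float, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Relative weight q(b, c) that host control gives a focal symbiont.

    ``q = exp(b c) / sum_b' exp((1-R) b' c) S(b') * exp(-f c)``.  The
    denominator measures the focal symbiont against the (relatedness-
    discounted) trait expression of its competitors; ``exp(-f c)`` is the
    blanket suppression cost of control.
    """
    _check_c(c, params)
    S.density = _check_density(S.density, "symbiont density")
    bgrid = params.b_grid.values
    denom = float(np.exp((1.0 - params.R) * bgrid * c) @ S.density)
    return float(np.exp(b * c) / denom * np.exp(-params.f * c))


def control_effect_matrix(
    S_density: np.ndarray, params: ModelParams, b_values: np.ndarray | None = None
) -> np.ndarray:
    """q(b, c) on the full (b-grid x c-grid), vectorized.

    ``S_density`` is the density used in the denominator, defined over
    ``b_values`` (defaults to the b-grid).
    """
    b = params.b_grid.values if b_values is None else np.ascontiguousarray(b_values)
    c = params.c_grid.values
    E, T, ef = _exp_tables(
        b.tobytes(), len(b), c.tobytes(), len(c), params.R, params.f
    )
    denom = T.T @ S_density  # (n_c,)
    return E / denom[None, :] * ef[None, :]


def mean_trait_after_control(
    c: float, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Mean symbiont cooperation bbar(c) after exponential control tilting.

    ``bbar(c) = sum q(b,c) S(b) b / sum q(b,c) S(b)``; the exp(-f c) factor
    cancels between numerator and denominator.
    """
    _check_c(c, params)
    S.density = _check_density(S.density, "symbiont density")
    b = params.b_grid.values
    w = np.exp(b * c) * S.density  # denominator of q and exp(-fc) cancel
    total = w.sum()
    if total <= 0.0:
        raise ValueError("degenerate symbiont density: zero total weight")
    return float((w @ b) / total)


def mean_trait_after_control_vector(
    S_density: np.ndarray,
    params: ModelParams,
    b_effective: np.ndarray | None = None,
    b_expressed: np.ndarray | None = None,
) -> np.ndarray:
    """bbar(c) over the whole c-grid.

    ``b_expressed`` is the trait the control exponent sees and
    ``b_effective`` the cooperation that is averaged; they coincide in the
    base model but differ in the trait-decoupling extension.
    """
    b_exp = params.b_grid.values if b_expressed is None else b_expressed
    b_eff = b_exp if b_effective is None else b_effective
    c = params.c_grid.values
    flat_exp = np.ascontiguousarray(np.asarray(b_exp, dtype=float).reshape(-1))
    E, _, _ = _exp_tables(
        flat_exp.tobytes(), len(flat_exp), c.tobytes(), len(c), params.R, params.f
    )
    w = E * np.asarray(S_density).reshape(-1)[:, None]  # (n_flat, n_c)
    denom = w.sum(axis=0)
    num = np.asarray(b_eff, dtype=float).reshape(-1) @ w
    return num / denom


def host_feedback(a: float, params: ModelParams) -> float:
    """Partner-fidelity feedback for the host: p_a = a * y."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"host cooperation {a} outside [0, 1]")
    return a * params.y


def symbiont_feedback(
    b: float, c: float, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Feedback benefit to a symbiont: p_b(c) = R b x + (1-R) bbar(c) x.

    Relatedness splits the feedback between the focal genotype's own
    cooperation (the clonal share) and the post-control population mean.
    """
    bbar = mean_trait_after_control(c, S, params)
    return params.R * b * params.x + (1.0 - params.R) * bbar * params.x


def host_fitness(
    a: float, c: float, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Host fitness W_a = (1-a) + x * (a y) * beta(bbar(c)) - g c/c_max."""
    bbar = mean_trait_after_control(c, S, params)
    benefit = benefit_transform(bbar, params.benefit_form)
    return (
        (1.0 - a)
        + params.x * host_feedback(a, params) * benefit
        - params.g * (c / params.c_max)
    )


def host_fitness_matrix(
    S_density: np.ndarray, params: ModelParams, bbar_c: np.ndarray | None = None
) -> np.ndarray:
    """W_a over the full (a-grid x c-grid)."""
    a = params.a_grid.values
    c = params.c_grid.values
    if bbar_c is None:
        bbar_c = mean_trait_after_control_vector(S_density, params)
    benefit = benefit_transform(bbar_c, params.benefit_form)
    return (
        (1.0 - a)[:, None]
        + params.x * params.y * np.outer(a, benefit)
        - (params.g * c / params.c_max)[None, :]
    )


def symbiont_fitness_between(
    b: float, H: HostPopulation, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Between-host symbiont fitness (colonisation of next-generation hosts).

    ``W_b = (1-b) + y * sum_{a,c} H(a,c) q(b,c) p_b(c) a``.
    """
    H.density = _check_density(H.density, "host density")
    S.density = _check_density(S.density, "symbiont density")
    a = params.a_grid.values
    c = params.c_grid.values
    total = 0.0
    for j, cj in enumerate(c):
        q = control_effect(b, cj, S, params)
        pb = symbiont_feedback(b, cj, S, params)
        total += float(H.density[:, j] @ a) * q * pb
    return (1.0 - b) + params.y * total


def symbiont_fitness_between_vector(
    H_density: np.ndarray,
    S_density: np.ndarray,
    params: ModelParams,
    *,
    b_effective: np.ndarray | None = None,
    b_expressed: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized between-host W_b over the symbiont grid.

    Supports the trait-decoupling extension through ``b_expressed`` (enters
    the control exponent) and ``b_effective`` (enters cost and feedback).
    """
    b_exp = params.b_grid.values if b_expressed is None else b_expressed
    b_eff = b_exp if b_effective is None else b_effective
    a = params.a_grid.values
    A_c = a @ H_density  # sum_a a H(a,c), shape (n_c,)
    flat_S = S_density.reshape(-1)
    flat_exp = np.asarray(b_exp).reshape(-1)
    flat_eff = np.asarray(b_eff).reshape(-1)
    q = control_effect_matrix(flat_S, params, b_values=flat_exp)  # (n_flat, n_c)
    bbar_c = mean_trait_after_control_vector(
        flat_S, params, b_effective=flat_eff, b_expressed=flat_exp
    )
    pb = (
        params.R * flat_eff[:, None] * params.x
        + (1.0 - params.R) * bbar_c[None, :] * params.x
    )
    W = (1.0 - flat_eff) + params.y * (q * pb) @ A_c
    return W.reshape(np.shape(b_eff))


def symbiont_fitness_within(
    b: float, H: HostPopulation, S: SymbiontPopulation, params: ModelParams
) -> float:
    """Within-host symbiont fitness (pure local growth-rate competition).

    ``W_b = (1-b) + sum_c q(b,c) h(c)`` with h(c) the marginal control
    density of the hosts the symbionts occupy.
    """
    H.density = _check_density(H.density, "host density")
    h = H.control_marginal()
    c = params.c_grid.values
    total = 0.0
    for j, cj in enumerate(c):
        total += control_effect(b, cj, S, params) * h[j]
    return (1.0 - b) + total


def symbiont_fitness_within_vector(
    H_density: np.ndarray,
    S_density: np.ndarray,
    params: ModelParams,
    *,
    b_effective: np.ndarray | None = None,
    b_expressed: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized within-host W_b over the symbiont grid."""
    b_exp = params.b_grid.values if b_expressed is None else b_expressed
    b_eff = b_exp if b_effective is None else b_effective
    h = H_density.sum(axis=0)
    flat_S = S_density.reshape(-1)
    flat_exp = np.asarray(b_exp).reshape(-1)
    flat_eff = np.asarray(b_eff).reshape(-1)
    q = control_effect_matrix(flat_S, params, b_values=flat_exp)
    W = (1.0 - flat_eff) + q @ h
    return W.reshape(np.shape(b_eff))
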