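"""Shared fixtures and independent scalar oracles.

The oracle functions re-derive every fitness/control quantity as plain
Python loops over grid points, straight from the model definitions, with no
vectorization and no code shared with the package internals.  They exist so
the vectorized implementations can be checked against an independent path.
"""

import math

import numpy as np
import pytest

from hostcontrol.model_core import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Headline parameter set (x=y=2, R=0.5, f=0.02, g=0.1, M=0.05, m=1e-6)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_symbiont_density(rng, n):
    return rng.dirichlet(np.ones(n))


def random_host_density(rng, n):
    return rng.dirichlet(np.ones(n * n)).reshape(n, n)


# --- independent scalar oracles -------------------------------------------

def oracle_q(b, c, S_density, b_grid, R, f):
    denom = sum(
        math.exp((1.0 - R) * bp * c) * sp for bp, sp in zip(b_grid, S_density)
    )
    return math.exp(b * c) / denom * math.exp(-f * c)


def oracle_bbar(c, S_density, b_grid, R, f):
    num = den = 0.0
    for bp, sp in zip(b_grid, S_density):
        q = oracle_q(bp, c, S_density, b_grid, R, f)
        num += q * sp * bp
        den += q * sp
    return num / den


def oracle_host_fitness(a, c, S_density, p: ModelParams):
    bbar = oracle_bbar(c, S_density, p.b_grid.values, p.R, p.f)
    return (1.0 - a) + p.x * (a * p.y) * bbar - p.g * (c / p.c_max)


def oracle_symbiont_fitness_between(b, H_density, S_density, p: ModelParams):
    a_grid, c_grid, b_grid = p.a_grid.values, p.c_grid.values, p.b_grid.values
    total = 0.0
    for i, a in enumerate(a_grid):
        for j, c in enumerate(c_grid):
            q = oracle_q(b, c, S_density, b_grid, p.R, p.f)
            bbar = oracle_bbar(c, S_density, b_grid, p.R, p.f)
            pb = p.R * b * p.x + (1.0 - p.R) * bbar * p.x
            total += H_density[i, j] * q * pb * a
    return (1.0 - b) + p.y * total


def oracle_symbiont_fitness_within(b, H_density, S_density, p: ModelParams):
    c_grid, b_grid = p.c_grid.values, p.b_grid.values
    h = H_density.sum(axis=0)
    total = 0.0
    for j, c in enumerate(c_grid):
        total += oracle_q(b, c, S_density, b_grid, p.R, p.f) * h[j]
    return (1.0 - b) + total
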