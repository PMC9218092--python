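"""Parameter sweeps and outcome classification for regime diagrams.

The deterministic model's equilibrium is a trait distribution, not a label;
for regime diagrams each run is classified against the environmental pool
baseline with a configurable margin.  A run counts as "cooperation" when
the final mean symbiont cooperation exceeds the pool mean by at least the
margin AND final mean host cooperation exceeds its initial value by at
least the margin — both partners must have moved, since mutualism requires
investment on both sides.  Control loss (final mean c under 10% of its
initial mean while control was enabled) is tracked as a separate flag
because it can co-occur with either label.
"""

from __future__ import annotations

import itertools
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .escape import EscapePhase, default_linked_pool, run_escape_simulation
from .evolution import (
    EnvironmentalPool,
    ExtinctionError,
    SimulationTrajectory,
    default_pool,
    run_simulation,
)
from .ibm import IBMConfig, run_ibm
from .model_core import ModelParams

__all__ = [
    "Outcome",
    "SweepSpec",
    "SweepResult",
    "classify_outcome",
    "run_sweep",
    "IBM_FIELDS",
]

LABELS = ("cooperation", "collapse", "control_lost", "extinct")
VARIANTS = ("base", "control", "escape", "ibm")

# IBMConfig fields addressable as sweep axes / fixed params
IBM_FIELDS = ("n_hosts", "microbes_per_host", "virulence", "pathogen_influx", "seed")
# axis aliases: one sweep axis driving several ModelParams fields
AXIS_ALIASES = {"benefit_xy": ("x", "y")}


@dataclass(frozen=True)
class Outcome:
    """Classification of a finished run."""

    label: str  # "cooperation" | "collapse" | "extinct"
    control_lost: bool
    final_mean_a: float
    final_mean_b: float
    final_mean_c: float

    @property
    def cooperative(self) -> bool:
        return self.label == "cooperation"


def _pool_mean_b(pool: EnvironmentalPool, params: ModelParams) -> float:
    dens = np.asarray(pool.density)
    b = params.b_grid.values
    if dens.ndim == 2:  # linked pool over (B, gamma): use effective b = gamma B
        return float((dens * np.outer(b, b)).sum())
    return float(dens @ b)


def classify_outcome(
    traj: SimulationTrajectory,
    pool: EnvironmentalPool,
    margin: float = 0.2,
) -> Outcome:
    """Label a trajectory as cooperation vs collapse relative to the pool.

    Enlarging the margin can only demote "cooperation" to "collapse",
    never the reverse.
    """
    if traj.n_generations == 0:
        raise ValueError("empty trajectory")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    params = traj.params
    pool_b = _pool_mean_b(pool, params)
    final_a, final_b = traj.mean_a[-1], traj.mean_b[-1]
    final_c, init_c = traj.mean_c[-1], traj.mean_c[0]
    cooperative = (final_b - pool_b >= margin) and (
        final_a - traj.mean_a[0] >= margin
    )
    control_lost = bool(
        params.control_enabled and init_c > 0 and final_c < 0.1 * init_c
    )
    return Outcome(
        label="cooperation" if cooperative else "collapse",
        control_lost=control_lost,
        final_mean_a=final_a,
        final_mean_b=final_b,
        final_mean_c=final_c,
    )


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian-product sweep over model parameters.

    ``axes`` maps parameter names (ModelParams fields, IBMConfig fields, or
    the alias ``benefit_xy`` for a joint x = y sweep) to value lists;
    ``fixed`` overrides defaults for all cells; ``variant`` selects the
    model: "base" (control disabled), "control" (control enabled),
    "escape" (linked model, gamma free), or "ibm".
    """

    axes: dict[str, list] = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    variant: str = "control"
    margin: float = 0.2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        valid = set(ModelParams.__dataclass_fields__) | set(IBM_FIELDS) | set(
            AXIS_ALIASES
        )
        for name in list(self.axes) + list(self.fixed):
            if name not in valid:
                raise KeyError(f"unknown sweep parameter {name!r}")

    @property
    def axis_names(self) -> list[str]:
        return list(self.axes)

    def combinations(self) -> list[dict]:
        names = self.axis_names
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]


@dataclass
class SweepResult:
    """Labelled grid: one row per parameter combination."""

    spec: SweepSpec
    frame: pd.DataFrame

    def count(self, label: str) -> int:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return int((self.frame["label"] == label).sum())


def _expand(settings: dict) -> dict:
    out = {}
    for k, v in settings.items():
        if k in AXIS_ALIASES:
            for target in AXIS_ALIASES[k]:
                out[target] = v
        else:
            out[k] = v
    return out


def _split_ibm(settings: dict) -> tuple[dict, dict]:
    ibm = {k: v for k, v in settings.items() if k in IBM_FIELDS}
    model = {k: v for k, v in settings.items() if k not in IBM_FIELDS}
    return model, ibm


def run_cell(spec: SweepSpec, combo: dict) -> Outcome:
    """Run one parameter combination of a sweep and classify it."""
    settings = _expand({**spec.fixed, **combo})
    model_kw, ibm_kw = _split_ibm(settings)
    if spec.variant == "base":
        model_kw.setdefault("control_enabled", False)
    params = ModelParams(**model_kw)
    if spec.variant in ("base", "control"):
        pool = default_pool(params)
        traj = run_simulation(params, pool)
    elif spec.variant == "escape":
        pool = default_linked_pool(params)
        traj = run_escape_simulation(
            params, [EscapePhase(params.n_host_generations, "free")], pool
        )
    else:  # ibm
        config = IBMConfig(params=params, **ibm_kw)
        pool = default_pool(params)
        traj = run_ibm(config, pool)
    return classify_outcome(traj, pool, spec.margin)


def run_sweep(spec: SweepSpec, cell_dir: str | Path | None = None) -> SweepResult:
    """Run every combination of a sweep and assemble the labelled grid.

    Cells are independent, so results do not depend on execution order.
    When ``cell_dir`` is given, each finished cell is written as a JSON
    file and existing cell files are reused, which makes an interrupted
    sweep resumable (only missing cells are recomputed).  Per-cell errors
    are recorded in the grid ("extinct" for extinction, "error" column
    otherwise) without aborting the sweep.
    """
    if cell_dir is not None:
        cell_dir = Path(cell_dir)
        cell_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, combo in enumerate(spec.combinations()):
        cell_file = cell_dir / f"cell_{idx:05d}.json" if cell_dir else None
        if cell_file is not None and cell_file.exists():
            rows.append(json.loads(cell_file.read_text()))
            continue
        row = dict(combo)
        try:
            outcome = run_cell(spec, combo)
            row.update(
                label=outcome.label,
                control_lost=outcome.control_lost,
                final_mean_a=outcome.final_mean_a,
                final_mean_b=outcome.final_mean_b,
                final_mean_c=outcome.final_mean_c,
                error="",
            )
        except ExtinctionError as exc:
            row.update(
                label="extinct", control_lost=False,
                final_mean_a=np.nan, final_mean_b=np.nan, final_mean_c=np.nan,
                error=str(exc),
            )
        except Exception as exc:  # recorded, not raised: sweep continues
            row.update(
                label="error", control_lost=False,
                final_mean_a=np.nan, final_mean_b=np.nan, final_mean_c=np.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
            row["traceback"] = traceback.format_exc(limit=3)
        if cell_file is not None:
            cell_file.write_text(json.dumps(row))
        rows.append(row)
    frame = pd.DataFrame(rows)
    return SweepResult(spec=spec, frame=frame)
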