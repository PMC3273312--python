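"""Replicated parameter sweeps: arrest-fraction phase portraits and
damage-optimality curves.

A sweep runs ``n_networks`` independent graph realisations times
``n_runs_per_network`` dynamics replicates for every cell of a
(tau_al, tau_bf, c_bf) grid, and aggregates per cell:

* the arrest fraction (runs arrested / runs) with its binomial standard
  error, the quantity plotted in the S-curve phase portraits; and
* mean fractional damage (pathological, apoptotic, total) at a fixed
  evaluation time, expressed as health units lost over total units
  ``m * w_max`` — the damage-optimality curves.

Seeding is deterministic and cell-independent: network m uses graph seed
``SeedSequence([base, 0, m])`` and replicate (m, k) uses dynamics seed
``SeedSequence([base, 1, m, k])``, so every cell sees the same networks and
the same random streams (paired replication), and results do not depend on
the order in which cells are evaluated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, run
from .graph import SpatialGraph, generate_graph

__all__ = [
    "SweepSpec",
    "SweepResult",
    "sweep_graphs",
    "run_cell",
    "run_sweep",
    "s_curve",
    "critical_cbf",
    "damage_curve",
    "write_sweep_csv",
    "read_sweep_csv",
]

SWEEP_COLUMNS = [
    "tau_al", "tau_bf", "c_bf", "n_total", "n_arrested", "arrest_fraction",
    "se", "frac_path_t20", "frac_apop_t20", "frac_total_t20",
]


@dataclass
class SweepSpec:
    """Grid and replication design for a sweep."""

    tau_al_values: Sequence[float]
    tau_bf_values: Sequence[float]
    c_bf_values: Sequence[float]
    n_networks: int = 10
    n_runs_per_network: int = 3
    horizon_T: int = 100
    eval_t: int = 20
    arrest_window: int = 3
    n: int = 400
    r: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_al_values", "tau_bf_values", "c_bf_values"):
            vals = list(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            setattr(self, name, vals)
        if self.n_networks < 1 or self.n_runs_per_network < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.horizon_T < 1:
            raise ValueError("horizon_T must be >= 1")

    def cells(self) -> list[tuple[float, float, float]]:
        return list(
            itertools.product(self.tau_al_values, self.tau_bf_values, self.c_bf_values)
        )


@dataclass
class SweepResult:
    """Tidy per-cell aggregate table (one row per grid cell)."""

    table: pd.DataFrame
    spec: SweepSpec | None = field(default=None, repr=False)

    def cell(self, tau_al: float, tau_bf: float, c_bf: float) -> pd.Series:
        t = self.table
        m = (
            np.isclose(t.tau_al, tau_al)
            & np.isclose(t.tau_bf, tau_bf)
            & np.isclose(t.c_bf, c_bf)
        )
        if not m.any():
            raise KeyError(f"no sweep cell ({tau_al}, {tau_bf}, {c_bf})")
        return t[m].iloc[0]


def graph_seed(base_seed: int, network: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, 0, network])


def dynamics_seed(base_seed: int, network: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, 1, network, replicate])


def sweep_graphs(spec: SweepSpec) -> list[SpatialGraph]:
    """The n_networks graph realisations shared by every cell of the sweep."""
    return [
        generate_graph(spec.n, spec.r, graph_seed(spec.base_seed, m))
        for m in range(spec.n_networks)
    ]


def run_cell(
    spec: SweepSpec,
    params: DynamicsParams,
    graphs: Sequence[SpatialGraph] | None = None,
) -> dict:
    """Run all replicates of one parameter cell and aggregate."""
    if graphs is None:
        graphs = sweep_graphs(spec)
    n_total = 0
    n_arrested = 0
    fracs = np.zeros(2)  # summed (path, apop) fractions
    for m, g in enumerate(graphs):
        units = g.m * params.w_max
        for k in range(spec.n_runs_per_network):
            rng = np.random.default_rng(dynamics_seed(spec.base_seed, m, k))
            ts, _, arrested = run(
                g, params, spec.horizon_T, rng, arrest_window=spec.arrest_window
            )
            cp, ca = ts.cumulative_at(spec.eval_t)
            n_total += 1
            n_arrested += int(arrested)
            if units:
                fracs += (cp / units, ca / units)
    p = n_arrested / n_total
    fp, fa = fracs / n_total
    return dict(
        tau_al=params.tau_al,
        tau_bf=params.tau_bf,
        c_bf=params.c_bf,
        n_total=n_total,
        n_arrested=n_arrested,
        arrest_fraction=p,
        se=float(np.sqrt(p * (1 - p) / n_total)),
        frac_path_t20=fp,
        frac_apop_t20=fa,
        frac_total_t20=fp + fa,
    )


def run_sweep(
    spec: SweepSpec,
    params_base: DynamicsParams | None = None,
    graphs: Sequence[SpatialGraph] | None = None,
    progress=None,
) -> SweepResult:
    """Evaluate every grid cell; infeasible parameter values yield NaN rows
    rather than aborting the sweep."""
    if params_base is None:
        params_base = DynamicsParams()
    if graphs is None:
        graphs = sweep_graphs(spec)
    rows = []
    for tau_al, tau_bf, c_bf in spec.cells():
        try:
            params = replace(params_base, tau_al=tau_al, tau_bf=tau_bf, c_bf=c_bf)
            row = run_cell(spec, params, graphs)
        except ValueError:
            row = dict(
                tau_al=tau_al, tau_bf=tau_bf, c_bf=c_bf,
                n_total=0, n_arrested=0, arrest_fraction=np.nan, se=np.nan,
                frac_path_t20=np.nan, frac_apop_t20=np.nan, frac_total_t20=np.nan,
            )
        rows.append(row)
        if progress is not None:
            progress(row)
    return SweepResult(table=pd.DataFrame(rows, columns=SWEEP_COLUMNS), spec=spec)


def s_curve(result: SweepResult, tau_al: float, tau_bf: float) -> pd.DataFrame:
    """Arrest fraction versus c_bf at fixed thresholds, sorted by c_bf."""
    t = result.table
    m = np.isclose(t.tau_al, tau_al) & np.isclose(t.tau_bf, tau_bf)
    if not m.any():
        raise KeyError(f"no cells with tau_al={tau_al}, tau_bf={tau_bf}")
    out = t[m].sort_values("c_bf").reset_index(drop=True)
    return out[["c_bf", "arrest_fraction", "se", "n_total"]]


def critical_cbf(curve: pd.DataFrame, tolerance: float = 0.0) -> float | None:
    """Smallest grid c_bf whose arrest fraction reaches 1 - tolerance.

    This is the critical firebreak factor above which (at tolerance 0) every
    simulation instance arrests; ``None`` if the curve never gets there.
    """
    if len(curve) == 0:
        raise ValueError("empty S-curve")
    ok = curve[curve.arrest_fraction >= 1.0 - tolerance]
    if len(ok) == 0:
        return None
    return float(ok.c_bf.iloc[0])


def damage_curve(result: SweepResult, tau_al: float, tau_bf: float) -> pd.DataFrame:
    """Mean fractional damages at the evaluation time versus c_bf."""
    t = result.table
    m = np.isclose(t.tau_al, tau_al) & np.isclose(t.tau_bf, tau_bf)
    if not m.any():
        raise KeyError(f"no cells with tau_al={tau_al}, tau_bf={tau_bf}")
    out = t[m].sort_values("c_bf").reset_index(drop=True)
    return out[["c_bf", "frac_path_t20", "frac_apop_t20", "frac_total_t20"]]


def write_sweep_csv(result: SweepResult, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# lesionnet sweep v1: " + ",".join(SWEEP_COLUMNS) + "\n")
        result.table.to_csv(fh, index=False)


def read_sweep_csv(path) -> SweepResult:
    return SweepResult(table=pd.read_csv(path, comment="#"))
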