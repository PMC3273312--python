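"""Convenience plots: damage time courses, S-curves, damage-optimality
curves and final network states.  Purely presentational; nothing here feeds
back into the simulation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import CAUSE_APOP, CAUSE_PATH, SimState, TimeSeries
from .graph import SpatialGraph
from .sweep import SweepResult, damage_curve, s_curve

__all__ = ["plot_timeseries", "plot_final_state", "plot_s_curves", "plot_damage_curves"]


def _save(fig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_timeseries(ts: TimeSeries, path) -> Path:
    """Instantaneous and cumulative damages per process, side by side."""
    df = ts.to_frame()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax1.plot(df.t, df.damaged_path, "*:", label="pathological")
    ax1.plot(df.t, df.damaged_apop, "o-", ms=3, label="apoptotic")
    ax1.set(xlabel="t", ylabel="instantaneous damage", title="per-step damage")
    ax1.legend()
    ax2.plot(df.t, df.cum_path, "*:", label="pathological")
    ax2.plot(df.t, df.cum_apop, "o-", ms=3, label="apoptotic")
    ax2.plot(df.t, df.cum_total, "s-", ms=3, label="total")
    ax2.set(xlabel="t", ylabel="cumulative damage", title="cumulative damage")
    ax2.legend()
    return _save(fig, path)


def plot_final_state(g: SpatialGraph, state: SimState, path) -> Path:
    """Final network: healthy edges dotted, apoptotic blue, pathological red."""
    fig, ax = plt.subplots(figsize=(5, 5))
    styles = {
        CAUSE_PATH: dict(color="darkred", lw=0.9, zorder=3),
        CAUSE_APOP: dict(color="royalblue", lw=0.9, zorder=2),
    }
    for j, (u, v) in enumerate(g.edges):
        cause = int(state.damage_cause[j])
        kw = styles.get(cause, dict(color="0.7", lw=0.4, ls=":", zorder=1))
        ax.plot(*g.coords[[u, v]].T, **kw)
    ax.scatter(*g.coords.T, s=4, c="black", zorder=4)
    ax.set(xlim=(0, 1), ylim=(0, 1), xticks=[], yticks=[])
    ax.set_aspect("equal")
    return _save(fig, path)


def plot_s_curves(result: SweepResult, path, vary: str = "tau_bf") -> Path:
    """Arrest fraction vs C_bf, one curve per value of the varied threshold."""
    fixed = "tau_al" if vary == "tau_bf" else "tau_bf"
    fig, ax = plt.subplots(figsize=(5, 3.5))
    t = result.table
    for fv in sorted(t[fixed].unique()):
        for vv in sorted(t[vary].unique()):
            kw = {fixed: fv, vary: vv}
            curve = s_curve(result, tau_al=kw.get("tau_al", fv), tau_bf=kw.get("tau_bf", vv))
            ax.errorbar(curve.c_bf, curve.arrest_fraction, yerr=curve.se,
                        marker="o", ms=3, label=f"{vary}={vv:g}")
        break  # one panel per fixed value; callers filter beforehand for more
    ax.set(xlabel="$C_{bf}$", ylabel="arrest fraction", ylim=(-0.05, 1.05))
    ax.legend(fontsize=7)
    return _save(fig, path)


def plot_damage_curves(result: SweepResult, tau_al: float, tau_bf: float, path) -> Path:
    """Mean fractional damages at the evaluation time vs C_bf."""
    curve = damage_curve(result, tau_al, tau_bf)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.c_bf, curve.frac_path_t20, "*:", label="pathological")
    ax.plot(curve.c_bf, curve.frac_apop_t20, "o-", ms=3, label="apoptotic")
    ax.plot(curve.c_bf, curve.frac_total_t20, "s-", ms=3, label="total")
    ax.set(xlabel="$C_{bf}$", ylabel="mean fractional damage")
    ax.legend()
    return _save(fig, path)
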