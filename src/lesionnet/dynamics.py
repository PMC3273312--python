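"""Per-timestep lesion dynamics on a spatial graph.

The model couples two damage processes on the edges (axons) of a fixed
radius random graph:

* a **pathological process** confined to a growing circular region of
  infection (ROI): each healthy edge with an endpoint inside the ROI loses
  one weight unit with probability ``p_damage`` per step, and the ROI radius
  grows by ``alpha * R_I(t) * roi0`` where ``R_I(t)`` is the per-step damage
  success rate;
* **programmed cell death** (apoptosis, the "firebreak"): nodes whose
  health fraction s_i/S_i has dropped below ``tau_al`` emit alarm signals of
  amplitude equal to the carrying edge's weight; nodes sum received signals,
  relay them once their accumulator reaches their own health s_i, and fire
  apoptosis once the accumulator reaches ``tau_bf * S_i``.  Firing kills
  every edge with an endpoint inside a disk of radius ``c_bf * roi0`` and
  silences the nodes in it.  Accumulators persist between timesteps until
  an apoptosis region resets them.

A timestep executes the substeps in a fixed order: pathological damage,
(optional) regeneration, ROI update, alarm generation, signal relay,
apoptosis, bookkeeping.  With the default two-state weights (w_max = 1) and
no regeneration, edge weights are binary and non-increasing in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import SpatialGraph, segment_point_distance

__all__ = [
    "CAUSE_NONE",
    "CAUSE_PATH",
    "CAUSE_APOP",
    "DynamicsParams",
    "SimState",
    "StepRecord",
    "TimeSeries",
    "init_state",
    "pathological_substep",
    "regeneration_substep",
    "update_roi",
    "generate_alarms",
    "relay_signals",
    "trigger_apoptosis",
    "step",
    "run",
    "write_timeseries_csv",
]

CAUSE_NONE = 0  # edge has never been driven to weight zero
CAUSE_PATH = 1  # first zeroed by the pathological process
CAUSE_APOP = 2  # first zeroed by programmed cell death


def _prob_vector(p, w_max: int, name: str) -> np.ndarray:
    v = np.broadcast_to(np.asarray(p, dtype=np.float64), (w_max,)).copy()
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    return v


@dataclass
class DynamicsParams:
    """All tunable model parameters.

    Defaults are the two-state reference configuration: binary edge weights,
    uniform damage probability 0.33, no regeneration, deterministic firing,
    lesion seeded at the center of the unit square with initial radius 0.05
    and growth constant 0.12.  ``tau_al = 0.7``, ``tau_bf = 0.5`` and
    ``c_bf = 1.5`` place the defaults in the fully-controlled regime.
    """

    w_max: int = 1
    p_damage: float | np.ndarray = 0.33
    p_regen: float | np.ndarray = 0.0
    p_apoptosis: float = 1.0
    tau_al: float = 0.7
    tau_bf: float = 0.5
    c_bf: float = 1.5
    alpha: float = 0.12
    roi0: float = 0.05
    lesion_center: tuple[float, float] = (0.5, 0.5)
    #: Model-variant switches (defaults define the reference model; see the
    #: methods note for the alternatives and why they exist):
    #: signal_mode  - "persistent": accumulators carry over between steps
    #:   until an apoptosis region resets them; "step": cleared every step,
    #:   so firing requires the threshold to be met within a single step.
    #: firing_norm  - apoptosis threshold compares the accumulator against
    #:   tau_bf * S_i ("S", max health) or tau_bf * s_i ("s", current).
    #: alarm_mode   - which nodes emit: "state" (pathologically damaged and
    #:   below tau_al, every step), "on_damage" (only on steps with new
    #:   pathological loss), "any_loss" (any health loss, every step),
    #:   "on_crossing" (one-shot on first dropping below tau_al).
    #: region_mode  - disk membership for edges: "endpoint" (either cell
    #:   body inside) or "segment" (the axon's segment meets the disk).
    #: kill_mode    - convention for the apoptosis kill set; "region"
    #:   follows region_mode, or override with "endpoint"/"segment"/"pair"
    #:   ("pair" = both endpoints inside, i.e. the edge lies in the disk).
    signal_mode: str = "persistent"
    firing_norm: str = "S"
    alarm_mode: str = "state"
    region_mode: str = "endpoint"
    kill_mode: str = "region"

    def __post_init__(self) -> None:
        if int(self.w_max) != self.w_max or self.w_max < 1:
            raise ValueError("w_max must be a positive integer")
        self.w_max = int(self.w_max)
        self.p_damage = _prob_vector(self.p_damage, self.w_max, "p_damage")
        self.p_regen = _prob_vector(self.p_regen, self.w_max, "p_regen")
        if not 0.0 <= self.p_apoptosis <= 1.0:
            raise ValueError("p_apoptosis must be in [0, 1]")
        if not 0.0 < self.tau_al < 1.0:
            raise ValueError("tau_al must lie in (0, 1)")
        if not 0.0 < self.tau_bf < 1.0:
            raise ValueError("tau_bf must lie in (0, 1)")
        if self.c_bf < 0.0:
            raise ValueError("c_bf must be nonnegative")
        if self.alpha < 0.0:
            raise ValueError("alpha must be nonnegative")
        if self.roi0 <= 0.0:
            raise ValueError("roi0 must be positive")
        self.lesion_center = (float(self.lesion_center[0]), float(self.lesion_center[1]))
        if self.signal_mode not in ("step", "persistent"):
            raise ValueError("signal_mode must be 'step' or 'persistent'")
        if self.firing_norm not in ("s", "S"):
            raise ValueError("firing_norm must be 's' (current health) or 'S' (max health)")
        if self.alarm_mode not in ("state", "on_damage", "any_loss", "on_crossing"):
            raise ValueError(
                "alarm_mode must be 'state', 'on_damage', 'any_loss' or 'on_crossing'"
            )
        if self.region_mode not in ("endpoint", "segment"):
            raise ValueError("region_mode must be 'endpoint' or 'segment'")
        if self.kill_mode not in ("region", "endpoint", "segment", "pair"):
            raise ValueError("kill_mode must be 'region', 'endpoint', 'segment' or 'pair'")


@dataclass
class SimState:
    """Mutable per-step simulation state (arrays indexed by edge or node)."""

    t: int
    weight: np.ndarray        # (m,) int, 0..w_max
    damage_cause: np.ndarray  # (m,) int8, CAUSE_* marks, first-touch
    signal_acc: np.ndarray    # (n,) float, accumulated alarm signal
    apoptotic_node: np.ndarray  # (n,) bool, inside a fired apoptosis region
    path_hit: np.ndarray      # (n,) bool, has lost weight to the pathological process
    path_hit_step: np.ndarray  # (n,) bool, lost weight pathologically this step
    alarmed: np.ndarray       # (n,) bool, has already emitted its (one-shot) alarm
    center_dist: np.ndarray   # (m,) float, distance of each edge to the lesion center
    roi: float                # current lesion radius
    s: np.ndarray             # (n,) int, current node health (sum of incident weights)
    S: np.ndarray             # (n,) int, maximum node health d_i * w_max
    cum_path: int = 0
    cum_apop: int = 0

    def recompute_health(self, g: SpatialGraph) -> None:
        s = np.zeros(g.n, dtype=np.int64)
        if g.m:
            np.add.at(s, g.edges[:, 0], self.weight)
            np.add.at(s, g.edges[:, 1], self.weight)
        self.s = s


@dataclass(frozen=True)
class StepRecord:
    t: int
    visited: int
    damaged_path: int
    damaged_apop: int
    R_I: float
    roi_after: float
    cum_path: int
    cum_apop: int

    @property
    def cum_total(self) -> int:
        return self.cum_path + self.cum_apop


@dataclass
class TimeSeries:
    """One StepRecord per executed step plus the final arrest verdict."""

    records: list[StepRecord] = field(default_factory=list)
    arrested: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                dict(
                    t=r.t,
                    visited=r.visited,
                    damaged_path=r.damaged_path,
                    damaged_apop=r.damaged_apop,
                    R_I=r.R_I,
                    roi=r.roi_after,
                    cum_path=r.cum_path,
                    cum_apop=r.cum_apop,
                    cum_total=r.cum_total,
                )
                for r in self.records
            ]
        )
        df["arrested"] = False
        if self.arrested and len(df):
            df.loc[df.index[-1], "arrested"] = True
        return df

    def cumulative_at(self, t: int) -> tuple[int, int]:
        """(cum_path, cum_apop) at time t; the final values if the run ended
        earlier (the series is stationary after arrest)."""
        best = (0, 0)
        for r in self.records:
            if r.t > t:
                break
            best = (r.cum_path, r.cum_apop)
        return best


def init_state(g: SpatialGraph, params: DynamicsParams) -> SimState:
    """Fully healthy state at t = 0 with the lesion seeded at ``roi0``."""
    weight = np.full(g.m, params.w_max, dtype=np.int64)
    S = g.degree * params.w_max
    state = SimState(
        t=0,
        weight=weight,
        damage_cause=np.zeros(g.m, dtype=np.int8),
        signal_acc=np.zeros(g.n, dtype=np.float64),
        apoptotic_node=np.zeros(g.n, dtype=bool),
        path_hit=np.zeros(g.n, dtype=bool),
        path_hit_step=np.zeros(g.n, dtype=bool),
        alarmed=np.zeros(g.n, dtype=bool),
        center_dist=_edge_point_distance(g, params.lesion_center, params.region_mode),
        roi=params.roi0,
        s=S.copy(),
        S=S,
    )
    if _eligible_mask(state, g, params).sum() == 0:
        warnings.warn(
            "initial lesion region contains no eligible edges; "
            "the simulation arrests trivially",
            stacklevel=2,
        )
    return state


def _edge_point_distance(g: SpatialGraph, point, region_mode: str) -> np.ndarray:
    """Distance from each edge to a point under the active region convention:
    nearest endpoint ("endpoint") or nearest point of the segment ("segment")."""
    if g.m == 0:
        return np.empty(0, dtype=np.float64)
    if region_mode == "segment":
        return segment_point_distance(g, point)
    point = np.asarray(point, dtype=np.float64)
    d = np.sqrt(np.sum((g.coords - point) ** 2, axis=1))
    return np.minimum(d[g.edges[:, 0]], d[g.edges[:, 1]])


def _eligible_mask(state: SimState, g: SpatialGraph, params: DynamicsParams) -> np.ndarray:
    """Healthy edges inside the ROI (region convention per params)."""
    if g.m == 0:
        return np.zeros(0, dtype=bool)
    return (state.weight > 0) & (state.center_dist <= state.roi)


def pathological_substep(
    state: SimState, g: SpatialGraph, params: DynamicsParams, rng: np.random.Generator
) -> tuple[int, int]:
    """Visit every healthy edge in the ROI; damage each by one unit with
    probability ``p_damage[weight - 1]``.  Returns (visited, damaged)."""
    state.path_hit_step[:] = False
    eligible = np.flatnonzero(_eligible_mask(state, g, params))
    visited = eligible.size
    if visited == 0:
        return 0, 0
    p = params.p_damage[state.weight[eligible] - 1]
    hit = eligible[rng.random(visited) < p]
    if hit.size:
        state.weight[hit] -= 1
        dead = hit[state.weight[hit] == 0]
        newly = dead[state.damage_cause[dead] == CAUSE_NONE]
        state.damage_cause[newly] = CAUSE_PATH
        state.path_hit[g.edges[hit, 0]] = True
        state.path_hit[g.edges[hit, 1]] = True
        state.path_hit_step[g.edges[hit, 0]] = True
        state.path_hit_step[g.edges[hit, 1]] = True
        state.recompute_health(g)
        state.cum_path += int(hit.size)
    return visited, int(hit.size)


def regeneration_substep(
    state: SimState, g: SpatialGraph, params: DynamicsParams, rng: np.random.Generator
) -> int:
    """Raise weights of below-maximum ROI edges by one unit with probability
    ``p_regen[weight]``.  A no-op in the default no-regeneration setup."""
    if not np.any(params.p_regen > 0):
        return 0
    mask = (state.weight < params.w_max) & (state.center_dist <= state.roi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    p = params.p_regen[state.weight[idx]]
    up = idx[rng.random(idx.size) < p]
    if up.size:
        state.weight[up] += 1
        state.recompute_health(g)
    return int(up.size)


def update_roi(state: SimState, R_I: float, params: DynamicsParams) -> float:
    """Grow the lesion radius by ``alpha * R_I * roi0``; growth-only, so the
    increment is zero when no damage succeeded."""
    if not 0.0 <= R_I <= 1.0:
        raise ValueError("R_I must lie in [0, 1]")
    state.roi = state.roi + params.alpha * R_I * params.roi0
    return state.roi


def _deposit(state: SimState, g: SpatialGraph, senders: np.ndarray) -> None:
    """Send amplitude-w(j) signals from each sender along all incident edges."""
    if senders.size == 0 or g.m == 0:
        return
    send = np.zeros(g.n, dtype=bool)
    send[senders] = True
    u, v = g.edges[:, 0], g.edges[:, 1]
    w = state.weight
    from_u = send[u]
    from_v = send[v]
    np.add.at(state.signal_acc, v[from_u], w[from_u])
    np.add.at(state.signal_acc, u[from_v], w[from_v])


def generate_alarms(state: SimState, g: SpatialGraph, params: DynamicsParams) -> np.ndarray:
    """Alarm emission: every pathologically damaged, non-apoptotic node whose
    health fraction s_i/S_i has fallen below ``tau_al`` sends a signal of
    amplitude ``weight[j]`` along each incident edge j.  Emission repeats
    every step while the node remains below threshold (dead edges carry
    amplitude zero, so fully disconnected emitters are effectively silent).
    Returns the emitting nodes."""
    if params.alarm_mode == "state":
        hit = state.path_hit
    elif params.alarm_mode == "on_damage":
        hit = state.path_hit_step
    elif params.alarm_mode == "any_loss":
        hit = state.s < state.S
    else:  # on_crossing: one-shot alarm, any cause of health loss
        hit = (state.s < state.S) & (~state.alarmed)
    ok = (~state.apoptotic_node) & hit & (state.S > 0)
    frac = np.where(state.S > 0, state.s / np.maximum(state.S, 1), 1.0)
    emitters = np.flatnonzero(ok & (frac < params.tau_al))
    _deposit(state, g, emitters)
    state.alarmed[emitters] = True
    return emitters


def relay_signals(state: SimState, g: SpatialGraph) -> np.ndarray:
    """Iterate signal relaying to a fixed point within the timestep.

    A node relays when its accumulated signal reaches its own current health
    s_i (and is positive), forwarding amplitude ``weight[j]`` along every
    incident edge; each node relays at most once per timestep, which bounds
    the cascade on cycles.  Returns all nodes that relayed."""
    relayed = np.zeros(g.n, dtype=bool)
    while True:
        can = (
            (~state.apoptotic_node)
            & (~relayed)
            & (state.signal_acc > 0)
            & (state.signal_acc >= state.s)
        )
        new = np.flatnonzero(can)
        if new.size == 0:
            break
        _deposit(state, g, new)
        relayed[new] = True
    return np.flatnonzero(relayed)


def trigger_apoptosis(
    state: SimState, g: SpatialGraph, params: DynamicsParams, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Fire programmed cell death and apply the firebreak.

    All non-apoptotic nodes whose accumulator has reached ``tau_bf * S_i``
    are candidates, evaluated simultaneously against the pre-apoptosis
    accumulators; each fires with probability ``p_apoptosis``.  Every edge
    with an endpoint within ``c_bf * roi0`` of a fired node is killed
    outright; nodes in the union of fired disks have their accumulators
    reset and are permanently silenced.  Returns (fired nodes, health units
    destroyed among previously healthy edges)."""
    ok = (~state.apoptotic_node) & (state.S > 0) & (state.signal_acc > 0)
    norm = state.s if params.firing_norm == "s" else state.S
    candidates = np.flatnonzero(ok & (state.signal_acc >= params.tau_bf * norm))
    if candidates.size and params.p_apoptosis < 1.0:
        keep = rng.random(candidates.size) < params.p_apoptosis
        fired = candidates[keep]
    else:
        fired = candidates
    if fired.size == 0:
        return fired, 0
    radius = params.c_bf * params.roi0
    d2 = np.sum(
        (g.coords[:, None, :] - g.coords[fired][None, :, :]) ** 2, axis=2
    )
    in_region = np.any(d2 <= radius * radius, axis=1)
    units = 0
    if g.m:
        kill = params.kill_mode if params.kill_mode != "region" else params.region_mode
        if kill == "pair":
            edge_hit = in_region[g.edges[:, 0]] & in_region[g.edges[:, 1]]
        elif kill == "segment":
            edge_hit = np.zeros(g.m, dtype=bool)
            for i in fired:
                edge_hit |= segment_point_distance(g, g.coords[i]) <= radius
        else:
            edge_hit = in_region[g.edges[:, 0]] | in_region[g.edges[:, 1]]
        killed = np.flatnonzero(edge_hit & (state.weight > 0))
        units = int(state.weight[killed].sum())
        newly = killed[state.damage_cause[killed] == CAUSE_NONE]
        state.damage_cause[newly] = CAUSE_APOP
        state.weight[killed] = 0
        if killed.size:
            state.recompute_health(g)
    state.signal_acc[in_region] = 0.0
    state.apoptotic_node[in_region] = True
    state.cum_apop += units
    return fired, units


def step(
    state: SimState, g: SpatialGraph, params: DynamicsParams, rng: np.random.Generator
) -> StepRecord:
    """Execute one full timestep and return its record.

    Substep order: pathological damage -> regeneration -> ROI update ->
    alarm generation -> signal relay -> apoptosis.  Apoptosis therefore
    responds to damage inflicted in the same step."""
    visited, damaged = pathological_substep(state, g, params, rng)
    regeneration_substep(state, g, params, rng)
    R_I = damaged / visited if visited else 0.0
    update_roi(state, R_I, params)
    if params.signal_mode == "step":
        state.signal_acc[:] = 0.0
    generate_alarms(state, g, params)
    relay_signals(state, g)
    _, apop_units = trigger_apoptosis(state, g, params, rng)
    state.t += 1
    return StepRecord(
        t=state.t,
        visited=visited,
        damaged_path=damaged,
        damaged_apop=apop_units,
        R_I=R_I,
        roi_after=state.roi,
        cum_path=state.cum_path,
        cum_apop=state.cum_apop,
    )


def run(
    g: SpatialGraph,
    params: DynamicsParams,
    T: int,
    rng,
    arrest_window: int = 3,
) -> tuple[TimeSeries, SimState, bool]:
    """Run up to ``T`` steps, stopping early once the lesion is arrested.

    Arrest is declared when both processes have produced zero instantaneous
    damage for ``arrest_window`` consecutive steps, or when no healthy edge
    remains inside the ROI.  ``rng`` may be a seed or a Generator.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    rng = np.random.default_rng(rng)
    state = init_state(g, params)
    ts = TimeSeries()
    quiet = 0
    for _ in range(T):
        rec = step(state, g, params, rng)
        ts.records.append(rec)
        quiet = quiet + 1 if (rec.damaged_path == 0 and rec.damaged_apop == 0) else 0
        if quiet >= arrest_window or _eligible_mask(state, g, params).sum() == 0:
            ts.arrested = True
            break
    return ts, state, ts.arrested


def write_timeseries_csv(ts: TimeSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# lesionnet timeseries v1: t,visited,damaged_path,damaged_apop,"
                 "R_I,roi,cum_path,cum_apop,cum_total,arrested\n")
        ts.to_frame().to_csv(fh, index=False)
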