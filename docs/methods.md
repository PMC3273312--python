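# Model and methods

## The network

The tissue is a fixed-radius random geometric graph G(n, r): n nodes (cell
bodies or functional units) i.i.d. uniform in the unit square, an
undirected edge (axon) for every pair at Euclidean distance ≤ r. "Within
distance r" is read as a closed ball; the tie is a measure-zero event and
the convention is fixed for reproducibility. The unit square has hard
boundaries (no periodic wrap), so nodes near the border have smaller
neighbourhoods; the lesion is seeded at the centre where boundary effects
are negligible. For the reference configuration n=400, r=0.2 the ensemble
mean degree is ≈ 41.9 = 399 · P(|X−Y| ≤ 0.2), with
P = πr² − 8r³/3 + r⁴/2 ≈ 0.105 (the disk-area expectation with boundary
correction); the degree distribution is approximately Gaussian. The
configuration n=4000, r=0.06 (with ROI₀ = 0.015) has a comparable mean
degree and behaves equivalently after rescaling.

Membership of an *edge* in a circular region is by default the **endpoint
convention**: an edge belongs to a disk iff at least one endpoint lies
inside. This ties damage to cell bodies and guarantees a non-empty seed
set when ROI₀ (0.05) is much smaller than r (0.2). A **segment
convention** (the axon's line segment intersects the disk) is available via
`DynamicsParams.region_mode="segment"`; it treats axons as spatially
extended and makes region membership independent of where the cell bodies
sit. See "Model variants" below.

## Dynamics

State per edge: integer weight w(j, t) ∈ {0, …, w_max} (w_max = 1 by
default: edges are alive or dead). Node health s_i(t) = Σ_j w(j, t) over
incident edges; S_i = d_i · w_max is the fully-healthy value. Each
timestep executes, in order:

1. **Pathological damage.** Every healthy edge inside the region of
   infection (ROI) is visited; each independently loses one weight unit
   with probability `p_damage[w−1]` (uniform p_d = 0.33 by default). The
   first process that drives an edge to weight 0 is recorded as its damage
   cause; causes are first-touch and never change.
2. **Regeneration** (off by default): below-maximum edges in the ROI gain
   one unit with probability `p_regen[w]`.
3. **ROI growth.** R_I(t) = damaged/visited (0 when nothing was visited);
   the lesion radius grows by α · R_I(t) · ROI₀. The rate is expressed in
   units of the initial lesion size so that outcomes are invariant to
   ROI₀ (verified as a test: halving ROI₀ leaves the arrest fraction
   unchanged within sampling error). The increment is non-negative: no
   mechanism in the model produces a negative rate, so "growth-only" is the
   only consistent reading.
4. **Alarms.** Every node that has lost weight to the pathological
   process, is not inside a fired apoptosis region, and whose health
   fraction s_i/S_i has fallen below τ_al emits a signal along each
   incident edge j with amplitude w(j, t) (dead edges carry nothing),
   added to the opposite endpoint's accumulator. Emission repeats each
   step while the condition holds. Larger τ_al means earlier alarms.
5. **Relay.** Iterated to a fixed point within the step: a node whose
   accumulator is positive and has reached its own current health s_i
   forwards amplitude w(j, t) along every incident edge, at most once per
   timestep (this bounds cascades on cycles). A node with s_i = 0
   formally relays but forwards amplitude zero, i.e. absorbs.
6. **Apoptosis.** All non-silenced nodes whose accumulator has reached
   τ_bf · S_i are evaluated simultaneously against the pre-apoptosis
   accumulators; each fires with probability p_p (default 1 — the
   probability is exposed but deterministic firing is the reference
   behaviour). Around every fired node, all edges touching the disk of
   radius C_bf · ROI₀ are set to weight 0 (healthy units destroyed are
   attributed to apoptosis unless the edge already had a cause); all nodes
   in the disk have their accumulators reset to zero and are permanently
   silenced — they emit no further alarms and never fire.

Signal accumulators persist across timesteps until an apoptosis region
resets them; without persistence, thresholds near 0.9 would be unreachable
in sparse regions. The τ_bf threshold is normalised by S_i for symmetry
with the τ_al rule.

**Arrest** is operationalised as: zero instantaneous damage from both
processes for `arrest_window` (default 3) consecutive steps, or no healthy
edge remaining inside the ROI. Runs stop at arrest; cumulative series are
stationary afterwards, so damage read-outs "at t = 20" use the final value
when a run arrested earlier.

### Accounting invariants

With regeneration off, edge weights are non-increasing, and at every step
cum_path + cum_apop equals the total health units lost
Σ_j (w_max − w(j, t)); no edge is double-counted across causes. These are
enforced by the test suite, including under multi-state weights
(w_max > 1).

## Model variants

The alarm/firing semantics of threshold-cascade models like this one admit
several readings that produce qualitatively different collective behaviour.
The reference model above is one consistent choice; the alternatives were
implemented and compared during development and remain available as
explicit switches on `DynamicsParams`:

* `signal_mode="step"` clears accumulators every step, so firing requires
  the threshold to be met within a single step. Firing then becomes a
  rare, late event at moderate thresholds: lesions at C_bf = 0.2 grow
  essentially unchecked with near-zero apoptotic damage, but containment
  at C_bf = 1.5 succeeds in only a minority of runs.
* `firing_norm="s"` compares the accumulator against τ_bf · s_i (current
  health): with per-step signals this makes firing a relative
  "fraction of my surviving neighbourhood in distress" condition.
* `alarm_mode` controls which nodes emit and how often: persistently while
  below threshold (`"state"`, default), only on steps with new
  pathological loss (`"on_damage"`), on any health loss whatever the cause
  (`"any_loss"` — lets apoptosis bystanders raise alarms), or one-shot at
  the first threshold crossing (`"on_crossing"`).
* `region_mode` / `kill_mode` choose the disk-membership convention for
  the lesion fuel and the apoptosis kill set independently (`"endpoint"`,
  `"segment"`, or for the kill set also `"pair"` = both endpoints inside,
  under which a small disk kills nothing).

Under the default (persistent) semantics, threshold crossings accumulate
wherever the lesion is active, so programmed cell death engages at every
C_bf and the lesion is eventually contained even when each firing destroys
little (the many small firings starve the front). Consequently the arrest
fraction at the reference thresholds (τ_al = 0.7, τ_bf = 0.5) is already
near 1 at small C_bf and the S-curve of arrest fraction versus C_bf is
compressed; C_bf still controls the *cost* of containment — mean total
damage at t = 20 rises steadily with C_bf above its critical value, and is
minimal near it. No single setting of the switches was found that
simultaneously yields a wide S-curve transition, a dominant-apoptosis
middle regime, and certain containment at C_bf = 1.5 under the reference
parameters; the variants bracket these behaviours and the default was
chosen as the internally consistent reference. This is the main known
limitation of the model as specified.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| n, r | nodes, connectivity radius | 400, 0.2 | —, unit-square lengths |
| w_max | maximum edge weight | 1 | health units |
| p_damage | per-visit damage probability per state | 0.33 | probability |
| p_regen | per-visit regeneration probability | 0 | probability |
| p_apoptosis | firing probability at threshold | 1 | probability |
| τ_al | alarm threshold on s_i/S_i | 0.7 | fraction |
| τ_bf | apoptosis threshold on acc/S_i | 0.5 | fraction |
| C_bf | apoptosis region factor (radius C_bf·ROI₀) | 1.5 | — |
| α | lesion growth constant | 0.12 | — |
| ROI₀ | initial lesion radius | 0.05 | unit-square lengths |
| lesion_center | seed position | (0.5, 0.5) | coordinates |
| T, arrest_window | horizon, quiet steps to declare arrest | 100, 3 | steps |

Defaults are the two-state reference configuration; τ_al, τ_bf, C_bf
default to the fully-controlled scenario (0.7, 0.5, 1.5).

## Sweeps and replication

A sweep cell (τ_al, τ_bf, C_bf) is replicated over `n_networks`
independent graphs × `n_runs_per_network` dynamics seeds. Seeding is
deterministic and cell-independent — graph m uses
`SeedSequence([base, 0, m])`, replicate (m, k) uses
`SeedSequence([base, 1, m, k])` — so all cells see identical networks and
random streams (paired replication) and results are independent of
evaluation order. Arrest fractions carry binomial standard errors
√(p(1−p)/N). At desk scale the default replication is 10 networks × 3
runs per cell (the phase portraits stabilise at far higher replication;
the reported standard errors make the sampling noise explicit). Damage
fractions are health units lost over total units m · w_max, read at
t = 20. The critical C_bf of an S-curve is the smallest grid value whose
arrest fraction reaches 1 − tolerance; tolerance defaults to 0 (strict
"all instances arrest") and is configurable because a single miss in N
replicates is likely at small N.

## Numerical and implementation notes

* Graph construction uses a k-d tree pair query; edge lists are stored
  canonically (u < v, lexicographic) so identical seeds give byte-identical
  graphs.
* All randomness flows through `numpy.random.Generator`; graph and
  dynamics streams are independent and separately seedable.
* Degenerate inputs: a lesion region containing no eligible edges warns
  and arrests trivially; p_damage = 0 arrests after `arrest_window` steps
  with zero damage; isolated nodes (S_i = 0) never emit or fire.
* Coordinates round-trip through GraphML/TSV at 17 significant digits.

## What the synthetic setting does and does not capture

The generator realises the study conditions themselves (uniform spatial
graphs, a single central lesion, homogeneous damage probabilities), so
passing tests demonstrate internal consistency of the mechanism, not
fidelity to biological lesion data: real CNS tissue has anisotropic,
modular connectivity, spatially heterogeneous vulnerability, multiple
simultaneous lesions, and regeneration. Continuous-time scheduling,
non-circular lesion geometry and 3-D embeddings are out of scope.
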