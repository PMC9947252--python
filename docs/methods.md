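# Methods

`replaynav` simulates a circuit model of flexible maze navigation in which
hippocampal replay both *learns* a value map and *reads it out* for
planning.  This note documents the model equations as implemented, the
numerical and design choices that were genuinely open, the desk-scale study
conditions, and what the simulations do and do not establish.

## Model

### Geodesic place code

`M` place cells sit on the cells of a square grid maze (pitch Δ).  The
firing rate of cell *i* when the animal is at **x** is

    r_i(x) = exp(−D(x_i, x) / σ),

where `D` is the shortest *around-wall* path length between grid cells,
computed by breadth-first search on the 4-connected free-cell graph (the
Lee routing algorithm).  Distances, not Euclidean offsets, determine both
the place fields and every synaptic structure derived from them; this is
what makes all downstream dynamics conform to the maze layout.  Continuous
positions are snapped to the nearest free cell; cells whose preferential
location is buried under a wall in the current layout are silent.  For the
experiments the population lives on the *full* grid so that cell identities
(and the synaptic matrices indexed by them) survive layout changes.

### Hebbian inter-PC learning

During exploration the recurrent matrix relaxes toward the rate
correlation,

    J ← J + α₁ (rᵀr − J),        fixed point  J*_ij = E[r_i r_j],

which decays with the geodesic distance between field centers and thereby
encodes the maze adjacency.  Updates are applied once per 0.6-s window of
the walk, using the window-averaged outer product.  With α₁ = 10⁻³ and
2,000 windows per session this gives α₁·n ≈ 2: about 86 % convergence with
a memory horizon spanning half the exploration — the same budget as one
update per locomotion period in the original protocol, while still
weighting every visited position.  (Per-sample updating at this α₁ would
remember only the last ~20 s of exploration.)

### From J to the network coupling

The raw correlation has two properties that matter for the dynamics:

* its magnitude scales inversely with the number of distinct visited
  locations, so it carries no absolute strength; and
* it is weighted by the exploration occupancy, which leaves weak links
  wherever the random walk under-sampled.

The coupling is therefore built as

    C = g · Ĵ + g_inh,   Ĵ_ij = J_ij / √(J_ii J_jj),

a cosine (occupancy-debiased) normalization — the analogue of homeostatic
synaptic scaling — rescaled so that the **median** coupling of adjacent
cell pairs equals the gain `g` (default 1.4), with uniform global
inhibition g_inh = −0.3.  The median over thousands of neighbour pairs is
stable across exploration histories to a fraction of a percent, whereas the
maximal entry fluctuates by tens of percent; pinning the median keeps the
network in the same dynamical regime for every learned J.  The diagonal is
excluded from the recurrent sum.

### Attractor network

Rates and feedback inhibition evolve as

    τ_r ṙ_i = −r_i + [Σ_{j≠i} C_ij r_j + E_i − I_i − h₀]₊
    τ_I İ_i = −I_i + c_I r_i

with τ_r = 2 ms, τ_I = 0.5 s, c_I = 10, h₀ = 0, integrated by explicit
Euler at Δt = 1 ms.  With h₀ = 0 and no input these dynamics are
positively homogeneous: activity either dies or grows without bound, while
the *shape* and trajectory of the bump are scale-invariant.  The
implementation bounds the fast variable by divisive peak normalization
(`r_cap` = 8): whenever the maximal rate exceeds the cap the rate vector
is rescaled to it.  The cap also positions the input-amplitude regimes:
peak feedback inhibition is c_I·r_cap = 80, so an input of amplitude 100
holds the bump while an input of 50 is periodically overcome.  The slow inhibition is left untouched, so it still
integrates activity and drives the bump along the maze.  States below
10⁻¹² are flushed to zero (numerically meaningless, and subnormals degrade
BLAS throughput ~40×).

Under the learned coupling the network supports a travelling activity
wave: excitation regenerates the bump ahead of its inhibition trail, and
the wave follows free-cell paths because the coupling vanishes across
walls.  A strong external input (A = 100) pins the bump at the input
center; with no input the wave wanders (rest replay); at intermediate
amplitude (A = 50) it periodically escapes and jumps back (awake
look-aheads).

### Replay as event trains

Rest replay is modelled as a train of discrete replay events, the analogue
of sharp-wave-ripple events: every `rest_event_duration` (2 s) the rates
are cleared and the 10-ms, amplitude-10 transient at the goal re-ignites
the bump.  The slow inhibition is *not* cleared, so each event is steered
away from recently replayed paths and the train progressively covers the
maze.  A bump that dies mid-event is re-ignited the same way.  A single
uninterrupted wander instead settles into a closed orbit covering a
fraction of the maze (deterministic dynamics have no other source of
variety).

Awake replay during planning is likewise a train of short probes
(`plan_event_duration` = 0.1 s) under the persistent amplitude-50 input at
the animal's position: the input re-ignites the home bump within
milliseconds of each reset, and because the inhibition persists, successive
probes escape along different paths.  One 1-s planning window thereby
samples the explorable directions, as the original description of awake
look-aheads requires; a single uninterrupted awake run yields only one or
two excursions and a direction menu that misses most headings.

Bump positions are decoded by a *local* population vector: the
activity-weighted mean over cells within 1 m (geodesic) of the most active
cell.  The global centroid would lie between coexisting bumps (the
look-ahead wave and the re-ignited home bump) and track neither.

### Three-factor striatal learning

During rest replay the PC→MSN weights follow

    Ẇ_i = α₂ z_i δ,    z_i = r̂_i V  (while r̂_i V > q),
    ż_i = −z_i/τ_z     (otherwise),
    δ   = G + V̇,      V = v₀ + W·r̂,   G = U·r̂,

with α₂ = 0.01 s⁻¹, q = 0.1, τ_z = 0.5 s, and U_i = exp(−D(x_i, x_g)/ξ),
ξ = 0.3.  Two implementation necessities:

* **Tonic MSN baseline v₀ = 1.** As printed, W(0) = 0 implies V ≡ 0,
  z ≡ 0, and the rule can never start.  The baseline (spontaneous MSN
  activity) breaks the deadlock inside the learning rule only; it is
  constant, so V̇ and all softmax decisions are unchanged.
* **Unit-peak rates.** The learning rule consumes the rate vector
  normalized to peak 1, the scale of the closed-form place fields for
  which q and α₂ are calibrated; fed the capped network rates directly,
  the quadratic trace diverges within seconds.

The trace is *replacing*: co-firing sets z to the instantaneous joint rate
instead of accumulating it, which prevents frequently replayed but
goal-distant places from being over-valued.  The decay branch uses the
exact exponential factor.  The eligibility trace is cleared at each event
boundary: a re-ignited bump is a new replay event, and stale traces from
the previous event's end would otherwise be credited by the goal transient
(measured, this flattens the value ramp).  V̇ is a backward difference,
defined as 0 at the first step of an event.  The rule is inherently
unstable at long horizons (weight growth is self-reinforcing through
z ∝ V); at α₂ = 10⁻² it is well-behaved for the 30–120 s phases used here
and collapses beyond roughly 250 s of cumulative learning, matching the
reported collapse of the rule above α₂ ≈ 10⁻².

After a goal change the goal weights are re-learned during re-exploration
by the reward-modulated rule U ← U + α₃ (r − U) applied whenever the
animal is inside the goal region (α₃ = 0.01 per recorded step; the rule is
global, so field components not supported by the rates at the rewarded
site decay — old goal associations extinguish).

### Planning and movement

Every 3 s the agent plans for 1 s and moves for 2 s at 0.5 m/s along one
of 8 compass headings.  The awake probe trace is segmented into
sub-trajectories — excursions of the decoded bump outside the disc of
radius d = 0.5 m around the animal — each carrying the initial direction
n = p(t₀) − x and the maximal MSN activity along its path.  Two details of
the scoring:

* the maximum is taken over the *open* interval (t₀, t₁): the re-entry
  sample, where the bump is back at the animal, would hand every excursion
  the home value;
* the maximum is restricted to the excursion's first 2 m of path
  (`lookahead`): long excursions curve, and value found after the bend
  says nothing about the initial direction the animal would follow.

The direction is sampled from the softmax P(k) ∝ exp(β·msnmax_k) with
β = 10.  The MSN read-out entering the softmax is scaled so that its peak
over free nodes is `value_scale` = 0.06, placing β·ΔV between greedy and
exploratory: decisive where the learned map is informative, stochastic
where it is flat (raw W magnitude is arbitrary — it grows with α₂·t).
Two embodiment priors stand in for the biomechanical body the kinematic
agent replaces: a turn cost (2 score units per half-turn, suspended after
collisions) makes the agent run straight when options are near-equivalent,
and headings whose first ~0.3 m are walled off are not selectable (an
animal pressed against a wall re-orients rather than pushing into it).
Movement integrates 1-ms sub-steps with wall collision (stopping for the
remainder of the period) and no diagonal corner-cutting.  All randomness
in a trial flows from one seeded generator.

## Study conditions (desk scale)

| quantity | value |
|---|---|
| maze | 8 × 8 m, 0.4 m pitch (20 × 20 cells, ~370 free) |
| place cells | full grid, M = 400, σ = 0.3 m |
| exploration | 20 trials × 60 s, heading re-drawn every 3 s, bounce at walls |
| Hebbian updates | α₁ = 10⁻³, one window-averaged update / 0.6 s |
| rest replay | 30 s (initial); 60 s after layout change; 120 s after a goal change |
| striatal stage | α₂ = 0.01 s⁻¹, q = 0.1, τ_z = 0.5 s, ξ = 0.3, v₀ = 1 |
| test trials | 25 starts spread over the maze, 120-s cap, goal disc radius 0.5 m |

The four mazes are hand-authored reduced replicas of the four experiment
layouts: a three-chamber maze whose two internal walls carry a passage at
each end; the detour closes one passage per wall; the shortcut removes the
east wall in three segments.  The goal-change target sits in the south
corridor, 3.2 m from the original goal.  The worst-case start-to-goal
geodesic in the detour maze is 12.8 m, reachable within the 120-s trial
cap at ~1 m of progress per 3-s decision cycle.

The goal-change rest period is 4× the from-scratch duration because
overwriting is slower than learning: instrumented at desk scale, the stale
value peak decays by only ~19 % per 120 s while the new peak grows
linearly, so the crossover takes several times the original learning time
— the same qualitative behaviour the original experiments report for
goal-change re-learning.

## What the simulations show — and what they do not

The desk-scale simulations demonstrate the full mechanistic chain:
layout-conforming replay emerges from a correlation-learned coupling;
replay plus the three-factor rule builds an MSN read-out that ramps toward
the goal; softmax planning over replay look-aheads navigates to the goal
and re-adapts after goal changes, closed passages, and new shortcuts.

They do not reproduce the original experiments' absolute numbers: the
reduced network (400 vs 2,500 cells, coarser pitch relative to σ) has a
rougher value map and a narrower excitability window, typical success
fractions are ~0.8–1.0 rather than uniformly 1.0, and the normalized
latency depends on the kinematic agent's fixed 0.5 m/s speed rather than
on a simulated body.  The per-node ramp monotonicity of the value map
(Spearman against negative geodesic distance) is strong near the goal but
degrades in the far field, where value is carried by few replay passes.
Deterministic dynamics are also a structural difference from any embodied
simulation: without the event-train structure and the embodiment priors
described above, the closed loop falls into exact behavioural cycles that
no amount of learning removes.

## Variant flags

* `simultaneous_updates` — learn W during exploration and J during replay
  as well (both rules active in both phases).
* `unified_equation` — drive exploration rates by the attractor dynamics
  under a persistent amplitude-80 input instead of the closed-form fields.
* `StriatalParams.trace_mode = "accumulating"` — conventional accumulating
  eligibility trace (ablation; over-values frequently replayed places).
* `CANParams.inhibitory_transfer` — threshold-linear transfer on the
  interneuron equation (control).
* `DecisionPolicy.goal_shape = "square"` — square goal region variant.
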