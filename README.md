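# replaynav

A desk-scale simulator of **layout-conforming hippocampal replay** and the
**replay-driven learning of flexible maze navigation**.

Place cells with *geodesic* firing fields — rates decaying with the
shortest around-wall path distance, `r_i(x) = exp(−D(x_i, x)/σ)` — learn
their recurrent coupling from exploration by a bounded Hebbian rule,
`J ← J + α₁(rᵀr − J)`, whose fixed point is the field correlation
`E[r_i r_j]`.  On that coupling, a continuous attractor network with slow
feedback inhibition,

    τ_r ṙ = −r + [J r + E − I − h₀]₊ ,    τ_I İ = −I + c_I r ,

produces a travelling activity bump that follows maze corridors and goes
*around* walls — replay that conforms to the layout.  During rest, replay
events ignited at the goal train the place-cell→striatum weights `W` with
a dopamine-modulated three-factor rule (replacing eligibility trace `z`,
teaching signal `δ = G + V̇` from goal cells and the MSN rate of change),
so that the striatal read-out `V = W·r` ramps up toward the goal.  During
navigation, the same network under an intermediate input generates
look-ahead excursions from the animal's position; the agent samples a
movement direction from the softmax `P(k) ∝ exp(β·max_t V)` over those
excursions.  Because every stage is built on geodesic structure, the whole
loop re-adapts when the goal moves, when passages close (detour), and when
walls are removed (shortcut).

The package is aimed at computational neuroscientists who want a compact,
fully inspectable implementation of this circuit — every phase (maze
geometry, place code, Hebbian learning, attractor dynamics, replay
segmentation, striatal learning, planning, and the four experiment
protocols) is a separate module with a plain-NumPy surface.

## Worked example

Run the goal-fixed experiment at desk scale (8×8 m three-chamber maze,
~370 place cells; exploration → rest-replay learning → 25 softmax-planned
test trials):

```python
from replaynav.experiments import ExperimentConfig, run_goal_fixed

cfg = ExperimentConfig(seed=1)
metrics, state = run_goal_fixed(cfg)
print(f"success rate:        {metrics.success_rate:.2f}")
print(f"normalized latency:  {metrics.normalized_latency:.2f} s/m")
print(metrics.trials.head(5))
```

which prints

```
success rate:        0.92
normalized latency:  5.83 s/m
 trial  start_x  start_y  success  time_to_goal  geodesic_to_goal
     0      0.2      0.2    False           NaN               8.0
     1      6.2      0.2     True        23.000               6.0
     2      4.2      0.6     True        13.731               3.6
     3      1.8      1.0     True        80.841               5.6
     4      7.8      1.0     True        22.436               6.8
```

`success rate` is the fraction of test trials that entered the 0.5-m goal
region within the 120-s cap; `normalized latency` is the mean time-to-goal
divided by the geodesic start→goal distance over successful trials (an
efficiency measure independent of the start position); the per-trial table
lists each fixed start, the outcome, and the geodesic distance it had to
cover.  `state` carries the learned synapses (`J`, `W`, `U`) and feeds the
follow-up experiments:

```python
from replaynav.experiments import run_goal_changing, run_detour, run_shortcut

m2, _  = run_goal_changing(cfg, state)   # goal moves; U and W re-learned
m3, s3 = run_detour(cfg, state)          # two passages close; J and W re-learned
m4, _  = run_shortcut(cfg, s3)           # walls removed; replay finds the shortcut
```

The same experiments are available from the shell:

```bash
replaynav experiment goal-fixed --seed 1 --out out/
replaynav sweep --parameter explore_trials --values 0,5,20 --seed 1
```

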