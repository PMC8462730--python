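# plaidpercept

Population-code simulations and psychophysics analysis for the question of
whether rats perceive the *global* motion direction of drifting plaids
(superpositions of two gratings drifting 120° apart), or only the *local*
motion of the constituent gratings.

The package has two halves:

1. **Neural simulations.** Populations of direction-tuned units with Von
   Mises tuning curves, `f(θ) = baseline + A·exp(k(cos(θ − θ_pref) − 1))`,
   split into *component* cells (tuned to the local directions of a plaid's
   constituent gratings, so their plaid tuning has two lobes separated by
   the cross-angle) and *pattern* cells (tuned to global direction, with
   identical grating and plaid tuning). A decision neuron — a logistic
   classifier minimizing cross-entropy + (λ/2)‖w‖² — is trained to
   discriminate 0° (rightward) from 180° (leftward) drifting stimuli and
   then probed with stimuli spanning the whole circle, yielding
   generalization curves (fraction of trials classified rightward per
   direction), decoding-pool pruning profiles (which cell class survives
   quantile-based weight pruning), and homeostatic norm analyses (how L2
   regularization rescales weights when cross-orientation suppression
   weakens one stimulus class).
2. **Behavioral analysis.** A pipeline for two-alternative
   forced-choice priming experiments: trial-validity filtering,
   learning-curve metrics (size-3 moving average, 70 %-over-4-days
   criterion, asymptotic accuracy), 19-point priming curves over
   prime–target angular distance, the priming-magnitude statistic (mean
   |accuracy − neutral| over the four most-coherent and four
   most-incoherent points), a 5 % inclusion criterion, session-level
   bootstrap (50 replicates) with Bonferroni-corrected normal 95 % CIs,
   and unpaired t-tests between groups. A synthetic-cohort generator with
   known injected priming bias provides ground truth for all of it.

## Worked example

Train the decision neuron on the 24-cell component representation and read
off the plaid generalization curve:

```python
from plaidpercept import ScenarioConfig, run_scenario

s = run_scenario(ScenarioConfig("fig4_component", seed=1))
print(s["prop_rightward_plaid_at_0_pct"])    # 100.0
print(s["prop_rightward_plaid_at_60_pct"])   # 3.2
print(s["plaid_local_max_direction_60_180"]) # 120.0
print(round(s["divergence"], 3))             # 0.451
```

The classifier always calls a 0°-drifting plaid rightward (it was the
training direction), almost never a 60° plaid (one constituent grating
lands on the negatively weighted units tuned near 120°), and recovers a
local maximum at 120° — the signature of a component-based code, whose
grating and plaid curves diverge strongly (mean absolute difference 0.45).
Running `"fig4_pattern"` instead gives a divergence of 0.010: a pattern
code treats gratings and plaids identically.

On the behavioral side, simulate a cohort (11 grating-trained "G" rats
primed only by gratings, 10 plaid-trained "P" rats primed by both) and
analyze it:

```bash
simulate-behavior --seed 3 --out runs/trials.csv --truth runs/truth.json
analyze-priming --trials runs/trials.csv --bootstrap-reps 20 --seed 4 --out runs/
```

which prints the group priming magnitudes (fractions):

```
G  identity 0.142   cross 0.055
P  identity 0.141   cross 0.141
```

— the G group's cross-priming magnitude collapses toward the sampling
floor of the absolute-value statistic while its identity priming stays
strong, and the P group's identity and cross magnitudes coincide,
mirroring the generator's injected biases (0.15 identity everywhere,
cross 0.02 for G and 0.15 for P).

## Scenarios

`plaidpercept run --scenario <name> --seed N --out dir/` runs a named,
fully seeded recipe and writes a JSON summary plus a reproducibility
manifest: `fig4_component`, `fig4_pattern`, `s2_sweep` (tuning-width sweep
k = 0.5…11), `s3_grating_trained`, `fig5_suppression` (1000-cell mixed
population, component plaid responses halved, pruning analysis),
`s4_control` (no suppression), `fig6_homeostatic` (pattern-only
population, plaid responses at 25 %, norm and evidence-curve analysis),
`behavior_synthetic`, `behavior_analysis`.

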