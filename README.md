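# touchbandit

Touchscreen operant chambers log the exact pixel coordinates and timing of
every choice response. `touchbandit` turns those logs into measurements of
latent cognitive state: it asks whether the explore/exploit trade-off, the
previous trial's reward, and sex change how *variable* the motor execution
of a two-arm restless bandit choice is, over and above which side was
chosen. It is written for behavioural and computational neuroscientists
running restless bandit (or similar two-choice) touchscreen tasks in
rodents, and for anyone who wants a tested reference implementation of the
analysis chain.

## What it implements

**Task.** A two-arm spatial restless bandit: on every trial each arm's
reward probability p has a 10% chance of stepping ±0.10, bounded to
[0.20, 0.90]; sessions are 300 trials. `task.simulate_walk` reproduces
these walks exactly (boundary handling is configurable: reflect or clamp).

**Explore/exploit labelling.** A 3-state hidden Markov model over the
left/right choice sequence with states explore, exploit-left,
exploit-right. Exploit states emit their side deterministically; explore
emits left with probability 0.5. Direct exploit-left ↔ exploit-right
transitions are structurally forbidden — leaving one aperture's exploit
state requires passing through exploration. Free parameters (the shared
exploit persistence a, the explore persistence b, the initial
distribution) are fitted by Baum–Welch EM on the constrained transition
matrix

```
         explore  exploit-L  exploit-R
explore  [  b      (1-b)/2    (1-b)/2 ]
exploit-L[ 1-a        a          0    ]
exploit-R[ 1-a        0          a    ]
```

and trials are labelled by Viterbi decoding (which cannot violate the
constraint), with the posterior P(explore) reported per trial.

**Choice model (RLCK).** A reinforcement-learning model with a choice
kernel: P(left) = σ(β(Q_L − Q_R) + b + κ(CK_L − CK_R)), delta-rule value
updates Q ← Q + α(r − Q), kernel traces tracking choice repetition with
the kernel learning rate tied to α — four free parameters (learning rate
α, decision noise β, side bias b, stickiness κ), fitted per animal by
bounded multi-restart maximum likelihood.

**Touch-precision metrics** (all in mm; 1 px = 0.29 mm on the 800 × 600
screen): successive-touch Euclidean distance √((x₂−x₁)² + (y₂−y₁)²)
restricted to consecutive same-side, same-state pairs (with full
exclusion accounting); Mahalanobis distance
[(X−c)ᵀ C⁻¹ (X−c)]^0.5 of each touch from its aperture/state centroid;
distance from the screen midline |400 − x|; response latency.

**Bouts.** Sessions segment into state episodes at explore↔exploit
transitions; episodes split by aperture side into bouts. Per bout:
centroid, successive-centroid shift distances, and the area/perimeter of
the outer boundary of a coarsened 2D density histogram (shoelace area on
the bin-edge-aligned outer contour).

**Statistics.** Linear mixed models (maximum likelihood, mouse-level
random intercepts/slopes) over the metric tables — e.g.
`dist_mm ~ sex × state + (state | mouse_id)` — with greedy backward
stepwise AIC selection that drops interactions before main effects and
never drops significant main effects.

**Synthetic cohorts.** `cohort.generate_cohort` produces full datasets
(default 16 mice/sex × 8 sessions × 300 trials) with planted structure —
tighter exploit touches, wider and midline-shifted explore touches, male
dispersion inflation, post-reward shrinkage, state/sex-dependent
latencies — plus the generating ground truth, so the whole pipeline is
testable end to end.

## Worked example

```python
import touchbandit as tb

cohort = tb.generate_cohort(tb.CohortConfig(n_per_sex=4, n_sessions=2), seed=7)
labeled, fits = tb.label_trials(cohort.trials, seed=7)
print(fits["F01"].summary())

pairs = tb.successive_euclidean(labeled)
print(pairs[pairs["included"]].groupby("state")["dist_mm"].mean())

fit = tb.fit_mixed_model(
    tb.ModelSpec("dist_mm", ("sex", "state", "sex:state"), "~state"),
    tb.state_metric_table(labeled),
)
print(fit.summary())
```

prints (abridged):

```
Constrained explore/exploit HMM (EM fit)
  sequences' total trials: 600   logL: -235.257   iterations: 89   converged: True
  stay_exploit = 0.9094
  stay_explore = 0.7327

state
exploit    5.64
explore    9.44

Mixed model (ML): dist_mm ~ sex + state + sex:state  [re: ~state | mouse_id]
  logL = -40.710  AIC = 97.421  k = 8  converged = True
  term                        beta          se           p
  Intercept                 8.8990      0.5488    3.89e-59
  sex                       1.1854      0.7761       0.127
  state                    -3.8536      0.5579    4.95e-12
  sex:state                 0.0015      0.7890       0.999
```

The fitted HMM recovers the persistence of exploit (0.91) and explore
(0.73) states used by the generator. Successive exploit touches land
5.6 mm apart on average versus 9.4 mm for explore touches, and the mixed
model attributes this to a strongly negative exploit coefficient
(state = −3.85 mm, p ≈ 5 × 10⁻¹²; exploit is coded 1); at this reduced
cohort size the male dispersion inflation (sex = +1.19 mm) does not
reach significance.

There is also a CLI mirroring the library stages:

```
touchbandit synth --seed 1 --out-dir data/
touchbandit label --in data/trials.csv --out data/labeled.csv
touchbandit run-all --seed 1 --out-dir run/
```

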