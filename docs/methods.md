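# Methods

This note documents the models, defaults and numerical choices behind
`touchbandit`, and what the synthetic-cohort tests do and do not
establish about real data.

## Restless walk

Each arm's reward probability performs an independent lazy random walk on
the grid {0.20, 0.30, …, 0.90}: with probability `step_prob` (default
0.10) per trial it steps ±`step_size` (default 0.10, direction
equiprobable), otherwise it stays. Values are re-rounded to 10 decimal
places after every update so the walk stays on the exact grid and the
bounds 0.20/0.90 are attained exactly.

*Boundary rule.* The task definition bounds the walk but leaves open what
happens when a step would cross a bound. Two rules are implemented:

- `reflect` (default): the step bounces back by its overshoot
  (0.90 + 0.10 → 0.80). Every attempted change is then a realized change,
  so the empirical per-trial change frequency equals `step_prob` — the
  defining rate of the task — for any occupancy of the boundary states.
- `clamp`: the step is absorbed at the bound. Outward steps at the bounds
  then produce no change, and the realized change frequency falls to
  ≈ 8.75% at the default parameters (the stationary distribution puts
  ≈ 1/4 of trials on a bound, half of whose attempted steps point
  outward). `reflect` is the default precisely because the 10% change
  rate is the task's stated property; `clamp` remains available for
  sensitivity analyses.

Initial probabilities are drawn uniformly from the grid when not fixed.
One `numpy` generator drives initialization, change indicators and step
directions in a documented order, so walks are bit-reproducible by seed.

## Explore/exploit HMM

States: explore (0), exploit-left (1), exploit-right (2). Exploit states
emit their side with probability 1; explore emits left with probability
0.5 (fittable via `fit_emission=True`). Deterministic exploit emissions
are what make the structural constraint meaningful: a side switch is
impossible without at least passing through explore. One persistence
parameter is shared by both exploit states and explore exits split
equally between them — the fewest parameters consistent with the allowed
transition diagram.

Fitting is Baum–Welch EM with the structural zeros held exactly: the
constrained M-step pools transition counts (explore persistence from the
explore row; exploit persistence from both exploit rows jointly), which
preserves the monotone-likelihood guarantee (asserted on every run).
Scaled (not log-space) forward/backward recursions handle the
deterministic emissions' zeros. Defaults: initialization at stay
probabilities 0.8/0.6 and a uniform initial distribution, 5 jittered
restarts, tolerance 1e-6, max 300 iterations; per-animal fitting across
sessions (pooled fitting is available via `label_trials(per="pooled")`).

Hard labels come from Viterbi decoding under the constrained matrix —
unlike per-trial MAP, the Viterbi path cannot contain a forbidden
transition — and the forward–backward posterior P(explore) is reported
alongside. Fitted at the generator's own conditions (persistence
0.9/0.7), per-trial explore/exploit recovery accuracy exceeds 0.85; this
is a regression bound for the synthetic process, not a claim about real
mice.

## RLCK agent

P(left) = σ(β(Q_L − Q_R) + b + κ(CK_L − CK_R)); chosen-arm delta rule
Q ← Q + α(r − Q) with Q initialized at 0.5; kernel traces CK start at 0
and move toward 1 (chosen) / 0 (unchosen) with the kernel learning rate
tied to α. Tying keeps exactly four free parameters (α, β, b, κ); the
policy and update live behind two small functions so an untied kernel
rate or a one-trial-back sticky indicator could be swapped in.

Fitting: L-BFGS-B on the summed negative log-likelihood over an animal's
sessions (agent state resets per session), bounds α ∈ [0, 1],
β ∈ [0, 20], b ∈ [−5, 5], κ ∈ [−10, 10], tolerance 1e-8, one fixed start
(0.5, 3, 0, 0) plus seeded uniform restarts (20 by default). Estimates
within 1e-6 of a bound set the corresponding `at_bound` flag (degenerate
behaviour such as all-left choosing pins bias/stickiness). Parameter
recovery at the study scale (8 × 300 trials): α within ±0.1 in ≥ 90% of
replicates.

## Metrics

All distances are converted at 0.29 mm/px; column names carry units.
Center distance uses |400 − x| on the x-coordinate alone — the apertures
differ only horizontally, and the vertical coordinate carries no
information about midline proximity. Successive Euclidean pairs never
span session boundaries and are excluded (with reason: side transition,
state transition, or both) whenever the two trials differ in aperture or
decoded state; an accounting identity (included + side-only + state-only
+ both = N − 1 per session) is asserted. Mahalanobis groups are built per
aperture and, when split, per explore/exploit touch population; groups
with fewer than 3 points or a singular covariance are skipped with a log
entry and NaN distances. Previous-reward conditioning drops each
session's first trial. Model tables average to the
mouse × session × state (× previous-reward) level before fitting,
mirroring session-averaged analyses.

Coordinates are stored screen-global; the `abet-export` reader dialect
converts aperture-local coordinates using the package's aperture-placement
convention (left window at x = 40, right at x = 520, both at y = 180,
240 × 240 px) — the placement is a convention because logged global
coordinates, not the mask geometry, are what the analyses consume.

## Bouts and contours

State episodes are maximal same-state runs; explore and exploit episodes
therefore alternate (|n_explore − n_exploit| ≤ 1 per session), and
episode counts are reported at the episode level. Side-splitting applies
only to spatial bouts: within an episode, touches on each aperture form
one bout, analysed separately. Centroids are componentwise means;
centroid shifts are Euclidean distances between successive same-state,
same-side bout centroids.

The density boundary of a bout: automatic (`numpy`) bin edges per axis,
coarsened by merging adjacent bin pairs ("every other edge"); counts
normalized to [0, 1]; the outer region is the set of bins whose
normalized density reaches the outermost of ten equal iso-levels
(`outer_level = 0.1`). Its boundary is traced by marching squares on the
zero-padded indicator grid, which places vertices exactly on bin edges.
This was chosen over interpolated iso-lines into the zero padding, which
systematically overestimate a known uniform support by ~15% at default
binning; the edge-aligned outline recovers a 20 × 20 mm uniform square's
area within a few percent. Disconnected outer components are summed (and
counted in `n_components`); nested boundaries are resolved by polygon
containment, keeping only top-level outlines. Bouts with fewer than 5
touches, or all-coincident touches, are flagged degenerate: they count
toward segmentation and centroid shifts but not area/perimeter. Area is
the shoelace sum, perimeter the summed edge lengths, both in mm.

## Mixed models and selection

Backend: `statsmodels` `MixedLM`, fitted by maximum likelihood (not
REML) so AIC is comparable across fixed-effect structures;
AIC = 2k − 2 logL with k = fixed coefficients + random-covariance
parameters + residual variance. Optimizers are tried in the order
L-BFGS-B, BFGS, Powell, accepting the first finite, convergent solution
(L-BFGS-B occasionally diverges silently on these likelihoods). Wald z
p-values are reported. Random structures with a singular fitted
covariance fall back to a random intercept and are flagged. Multiple
additive random-slope blocks (e.g. independent reward and state slopes)
are represented as a single correlated random block — `MixedLM` supports
one block per group — which nests the intended structure.

Factors are treatment-coded: sex M = 1 vs F = 0, state exploit = 1 vs
explore = 0, previous reward rewarded = 1. Coefficient signs depend on
this coding and the report prints it.

Stepwise selection is a greedy backward AIC descent: children drop one
droppable term each (interactions are always droppable; a main effect
only when no remaining interaction involves it and its parent-fit p ≥
0.05 — significant main effects are never dropped), the lowest-AIC child
is adopted while AIC strictly improves, ties break toward fewer
parameters, and failed child fits are skipped with a log entry. Random
structures are held fixed at the starting specification: the winning
random structure differs per analysis and is supplied with each starting
model, keeping the search over fixed effects well-defined. The
previous-reward analysis starts from a family including previous reward
and all its pairwise interactions.

## Synthetic cohorts

Defaults encode the study design: 16 mice per sex, 8 sessions of 300
trials, latent chains from the constrained HMM at persistence 0.9
(exploit) / 0.7 (explore). Exploit states force their side; explore
choices are fair coin flips by default. The alternative `rlck` explore
policy draws explore choices from the animal's RLCK policy — more
realistic choice statistics, but its sticky explore choices violate the
labeler's 50/50 explore emission and bias the recovered explore
persistence by ≈ −0.2, so the matched-assumptions policy is the default
study condition and the mismatch case is available for robustness work.

Touches are truncated (clipped) bivariate Gaussians centred on the
chosen aperture: exploit SD 2.5 mm, explore SD 5.0 mm with the explore
mean shifted 8 mm toward the screen midline; male dispersion × 1.3;
post-reward dispersion × 0.8; per-mouse lognormal dispersion
heterogeneity (σ = 0.10) so sex contrasts are honest between-animal
comparisons. Latencies are lognormal (σ = 0.4) with medians 2.0 s
(explore) / 1.4 s (exploit), × 1.25 in males, with per-mouse lognormal
heterogeneity (σ = 0.10). These magnitudes were chosen once as plausible
for mouse touchscreen responding (millimetre-scale nosepoke scatter on a
70 mm aperture, seconds-scale latencies) and produce unambiguous planted
effects at the study's sample size; they are study conditions, not
tuning knobs.

What the generator does *not* model: reward-driven state transitions
(the latent chain is independent of outcomes), biomechanics of reaching,
session fatigue, aperture-specific biases, or heavy-tailed touch
scatter. Passing planted-effect tests therefore shows the pipeline
recovers effects of the assumed form at the assumed scale — not that
real mice exhibit them.

## Problem sizes in the test suite

Oracle tests enumerate all 3^T paths at T ≤ 8. Recovery tests run 50
HMM sequences / 50 RLCK replicate fits. End-to-end planted-effect and
null-calibration checks use 12 full-size cohorts each (16/sex, 8 × 300),
fitting the previous-reward Euclidean model per cohort; 12 replicates
resolve the ≥ 90% recovery criterion (failures would need ≥ 2/12) and 36
null p-values bound the false-positive rate. The walk-statistics check
uses 100 walks × 10,000 trials.

## Known limitations

- Wald z p-values from `MixedLM` are mildly anti-conservative for
  between-mouse effects at n = 32 animals compared with Satterthwaite t
  approximations.
- The contour boundary depends on the automatic binning rule; absolute
  areas are resolution-dependent and only relative comparisons across
  states/sexes are contractually meaningful.
- The RLCK functional form is the standard softmax-with-choice-kernel
  with a tied kernel learning rate; alternative stickiness
  parameterizations fit behind the same two functions but are not
  implemented.
- Exclusion percentages and bout counts on real datasets depend on the
  empirical state sequence; the synthetic defaults do not target any
  particular published value of those descriptive statistics.
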