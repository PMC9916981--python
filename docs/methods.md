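# Methods

`hypkernel` turns qualitative hypotheses of the form "emotion *e* is
expressed with action units *a₁ + a₂ …*" into predictive classifiers and
evaluates, explains, and optimizes them against forced-choice
categorization behavior. This note documents the model, its assumptions,
the numerical choices, and what the bundled simulator does and does not
show.

## The canonical AU space

Stimuli are parameterized by facial action units (AUs). The generative
vocabulary mixes compound AUs (`1+2`, `6+12`, `12+25`), unilateral AUs
(`12L`, `12R`), and bilateral AUs (`12`, meaning both sides). To treat
each AU as an independent variable, compounds are expanded into their
constituents and bilateral AUs into separate left/right variables,
yielding a fixed, ordered space of P = 33 AUs:

```
1, 2L, 2R, 4, 5, 6L, 6R, 7L, 7R, 9, 10L, 10R, 11L, 11R, 12L, 12R, 13,
14L, 14R, 15, 16, 17, 20L, 20R, 22, 23, 24, 25, 26, 27, 38, 39, 43
```

(in canonical order; eight numbers — 2, 6, 7, 10, 11, 12, 14, 20 — are
lateralized). When two raw labels reach the same canonical AU, the
maximum amplitude wins by default ("active" semantics); a sum-clipped-at-1
rule is available. A hypothesis that references a bilateral number (e.g.
"happy = 6 + 12") activates both laterals. One published model references
AU19, which has no canonical counterpart in the stimulus space; the
registry loader drops it and records the drop on the model rather than
failing, since the AU can never contribute signal.

## Hypothesis kernel analysis

A model **M** maps each category to one or more *configurations* —
vectors in AU space, binary for theory models, weighted in [0, 1] for
data-driven models. A stimulus **s** is the vector of its peak AU
amplitudes. Prediction proceeds in three steps:

1. **Similarity.** Each category's score is the kernel similarity between
   the stimulus and that category's configurations, taking the maximum
   over configurations when there are several ("the set with the largest
   similarity"). The default kernel is the cosine,
   k(u, v) = uᵀv / (‖u‖‖v‖), defined as 0 when either norm vanishes; dot
   product and negative-Euclidean kernels are pluggable alternatives.
2. **Softmax.** Scores become category probabilities through
   softmax(β·scores) over the model's covered categories. β (default 1)
   is a calibration parameter.
3. **Scoring.** Predictive performance is the one-vs-rest AUROC of each
   category's probability column against the binary indicator of that
   category being chosen, computed per participant. AUROC is the
   Mann–Whitney probability that a random positive outranks a random
   negative, ties counting one half; chance is 0.5, the maximum 1.
   Single-class cells (a participant who always or never chose a
   category) are undefined: they are recorded as skips, never imputed as
   0.5, and excluded from averages.

Two properties deserve explicit statement because they are exact only in
restricted cases:

* For a **binary** (two-category) model the probability columns are
  complements, so both classes receive the same AUROC, and the ranking is
  exactly independent of β. With more categories, β re-weights how
  competing categories discount a score; the effect on AUROC is small
  (≈0.01 across β ∈ [0.5, 8] in our simulations) but not zero. β = 1 is
  the default everywhere and all reported numbers use it.
* A responder that answers with the argmax of a model's own predictions
  does **not** generally produce per-category AUROC = 1: argmax
  guarantees the top category within a trial, not separation of a
  category's scores across trials. Exact AUROC = 1 requires scores that
  strictly separate positives from negatives — e.g. stimuli that are
  scaled copies of the configurations (cosine is scale-invariant).

## Noise ceiling

No model that sees only the stimulus can beat the true conditional label
distribution P(category | stimulus). The plug-in ceiling estimates that
conditional empirically from all observations sharing a stimulus key (a
hash of the exact AU pattern, amplitudes rounded to 6 decimals) and
scores it with the same one-vs-rest AUROC. It is an upper bound but an
*optimistic* one: each trial's own label enters its conditional, and with
m observations per stimulus the bias under pure noise is visible (with 60
observations of label-randomized stimuli the plug-in ceiling is ≈0.58,
not 0.5). The leave-one-participant-out mode excludes the trial's own
participant from the conditional and recovers chance (≈0.50) in the same
setting; it is the mode to use when the ceiling itself is the quantity of
interest. The mode is always recorded in the report.

Stimuli observed once contribute their own label as "distribution" and
saturate the plug-in estimate; the report carries the singleton fraction
(warning above 50%) and a `min_observations` filter restricts estimation
to the repeated-stimulus block. Uncertainty comes from bootstrapping
observations within each stimulus-key group (default 1,000 resamples,
seeded). Ceilings may be estimated pooled or per culture; the grouping is
named in the report.

## Explanation by ablation, exploration by accenting

Ablation removes one AU (both laterals for a bilateral number) from every
configuration of one category of one model, drops emptied configurations,
and re-evaluates. The ablation map holds mean ΔAUROC (ablated − original,
averaged over participants, then over the models containing that AU);
cells for AUs in no model's category are undefined and never enter
averages. Ablating an absent AU is an error, not Δ = 0 — the two must not
be conflated. Δ < −ε marks an AU performance-critical, Δ > +ε
performance-detrimental (strict signs; the dead zone ε defaults to 0).
Criticality is decided from the across-model average and then applied to
every model. Whether ablation should remove an AU from all categories
simultaneously is an open design question; this package removes it from
the target category only, matching the per-emotion framing of the
procedure.

Optimization adds every critical AU to, and removes every detrimental AU
from, each configuration of the category, per culture. A category whose
configurations would all vanish keeps its original configuration of
largest total weight and is flagged ("best" is not otherwise defined; the
largest configuration preserves the most structure).

Cross-validation: per culture, participants split 2/3 train / 1/3 test
(60 → 40/20), faces 50/50, stimulus keys 50/50. Train trials are
train-participant trials with train faces *and* train keys; test trials
likewise; off-diagonal trials are dropped and the fraction reported
(≈75% under this two-way crossing — the price of guaranteeing that test
stimuli contain unseen AU patterns and unseen faces). Ablation maps and
accents are derived from train data only; the split's disjointness is
asserted inside the pipeline, not only in tests. Culture comparisons are
two-sided pooled-variance independent t tests on per-participant,
model-averaged AUROCs with pooled-SD Cohen's d (first culture minus
second; WE − EA by default), uncorrected for multiple comparisons and
flagged as such.

## Data-driven model estimation

Per participant, category and AU: the point-biserial Pearson correlation
between AU amplitude and the chose-this-category indicator; two-sided p
from the t transform with n − 2 degrees of freedom; a cell is significant
at uncorrected α = 0.05. The default sign rule requires r > 0 — a
significantly negative correlation should not add an AU to a category's
template; a sign-agnostic rule is switchable. Constant amplitude columns
and single-class categories are undefined and count as not significant.
Per-participant binary matrices are aggregated by proportion weighting
(significant in 90% of participants → weight 0.9) or by strict majority
(> 50% → binary model). The weighted row vector becomes a single
continuous configuration per category; zero-weight categories are left
uncovered. Leave-one-participant-out evaluation fits the N−1 others,
aggregates, and scores the left-out participant, so the estimate is never
evaluated on its own training data. The order of operations — binarize
per participant by significance, then aggregate across participants — is
the only reading consistent with the majority rule and the
proportion-weight example.

## The behavior simulator

The simulator emulates the structure of a random-expression
categorization study so that every stage runs and is validated without
external data. Stimuli: AU count ~ Binomial(n = 5, P = 0.6) with zero
draws resampled (an expressionless face cannot be categorized),
amplitudes ~ U(0, 1), labels drawn from a 42-label generative vocabulary
(3 compounds + 14 unilaterals + 25 bilateral numbers — a declared
stand-in; the original vocabulary's exact composition is unpublished),
recoded into canonical space; 8 faces per culture. Six temporal
parameters per AU are drawn for structural fidelity and ignored — only
peak amplitude is analyzed.

Responders are softmax perceivers: with probability λ (lapse, default
0.1) a uniform random category; otherwise "other" when the best category
similarity under the responder's own model falls below τ (default 0.22),
else a draw from softmax(β_p·scores) (β_p default 8). Each participant's
model deviates from the culture template by flipping each (category, AU)
membership with probability π (idiosyncrasy, default 0.04). τ, β_p and π
were calibrated once so that the simulated marginals sit at a realistic
operating point — ≈15% "other" responses and a repeated-block noise
ceiling near 0.88, the regime reported for this kind of experiment — and
then frozen.

The default two-culture experiment gives WE responders one published
model's configurations verbatim and EA responders the same model with
planted accent edits (per category: one ensemble-emphasized AU removed,
one ensemble-peripheral but ensemble-present AU added; edits are globally
distinct across categories so both cultures are equally identifiable
intrinsically). This instantiates the phenomenon the framework is built
to detect: the tested models sit closer to one culture's behavior, the
ablation stage recovers the planted accents per culture, and optimized
culture-accented models erase the bias on held-out data.

**What passing simulations do not show.** The simulator's perceiver is
the same functional family the kernel analysis assumes (cosine + softmax
over an AU template), so recovery results validate the machinery — the
estimators, the cross-validation hygiene, the causal logic of ablation —
not the adequacy of linear AU templates for real human perception. Real
faces carry identity, texture and temporal information that no AU-only
model sees; real noise ceilings reflect genuine individual differences,
not the π/λ mechanism. Default problem sizes (60 participants per
culture × 1,200 trials; 100-stimulus shared block) are half the trial
count of the study the structure mirrors, chosen to keep a full cycle at
desk scale.

## Numerical choices and degenerate inputs

* AUROC via average ranks (`scipy.stats.rankdata`); exact agreement with
  the O(n²) pairwise oracle is enforced in tests, including ties.
* Zero-norm stimuli have similarity 0 to every configuration → uniform
  predictions.
* Softmax is computed with the row-max subtracted; probability rows sum
  to 1 within 1e-9.
* Stimulus keys round amplitudes to 6 decimals before hashing
  (configurable); equal patterns hash equally regardless of AU order.
* Duplicate configurations arising from notation expansion are removed;
  multi-configuration models are not otherwise normalized (simulation
  evidence in the source literature indicates the max rule does not
  unfairly advantage models with more configurations).
* Splits, bootstraps and simulations consume a single seeded
  `numpy.random.Generator` per run; identical seeds reproduce outputs
  byte-identically.

## Known limitations

* Table-derived conversational-signal model configurations are not
  bundled (unpublished in the accessible sources); the registry ships
  five named empty slots that accept user specifications.
* The plug-in noise ceiling is optimistic for sparsely repeated stimuli;
  use the leave-one-participant-out mode or `min_observations=2` when the
  ceiling is the estimand.
* One explanation→exploration pass only; no iterative re-ablation of
  optimized models.
* No probability calibration and no confusion-matrix headline metrics.
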