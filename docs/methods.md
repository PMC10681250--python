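# Methods

## Outcome model

The end-of-treatment outcome is reliable improvement (RI), a
Jacobson–Truax-style reliable-change criterion on self-reported symptom
totals:

- RI in depression: PHQ-9 decreases by at least 6 points between the first
  (baseline) and last available measure, and GAD-7 does not increase by 4
  or more points.
- RI in anxiety: GAD-7 decreases by at least 4 points and PHQ-9 does not
  increase by 6 or more points.

An increase of exactly the disqualifying threshold already revokes the
label ("no increase ≥ k" is read literally with a strict complement).
Labels are computed under last-observation-carried-forward: for clients
with fewer than eight reviews, the last observed totals at or before
review 8 stand in for the end-of-programme scores. Baseline is the first
completed measure. Severity bands fix only the mild upper edge (PHQ-9 ≤ 8,
GAD-7 ≤ 6) as required by the subgroup analysis; the moderate/severe split
(PHQ-9 9–16/17–27, GAD-7 7–14/15–21) follows conventional instrument
banding and is overridable.

## Synthetic cohort generator

The generator emulates a supported iCBT service population so that every
downstream stage is testable without clinical data. Each client draws:

1. a latent **trajectory archetype** shared by both instruments — steady
   improver, sudden-gain improver, late improver, non-responder, or
   deteriorator — whose mean cumulative change curve (on the PHQ-9 scale,
   scaled by 0.8 onto GAD-7) spans eight reviews;
2. **baseline totals** per instrument from a severity mixture (defaults:
   25% mild / 45–50% moderate / 25–30% severe), uniform within band;
3. total-score series: baseline + curve + bivariate Gaussian observation
   noise (SD 2.5 points, PHQ/GAD correlation 0.6), rounded and clipped to
   the instrument range; review 1 equals the baseline exactly;
4. **item scores** by a constrained random partition of each total into
   9 (or 7) items capped at 3 — trajectories are generated on totals and
   allocated downward because the outcome operates on totals; item-level
   structure is only needed by the Qc feature set;
5. **interaction counts** per review: a negative-binomial total (mean
   proportional to an archetype-specific engagement level, dispersion 4)
   thinned over a small random subset of the 1133-type taxonomy via a
   Dirichlet–multinomial split — overdispersed and sparse, as platform
   event counts are;
6. **review intervals** Gaussian with mean 1.8 / SD 0.24 weeks, truncated
   at 0.5; intervals are metadata only — prediction time is the review
   index;
7. **dropout** after each completed review from the second onward, with a
   per-review hazard following a logistic link in the client's current
   PHQ-9 improvement (base hazard 0.5 at zero improvement, coefficient
   0.2). The positive coupling — improved clients leave earlier — reflects
   that many clients complete treatment or reliably improve before the
   intended programme length, and is what lets the shipped conditions
   jointly reproduce three facts about such cohorts: about 60% of clients
   with fewer than three reviews, RI prevalences near 26% (PHQ-9) and 38%
   (GAD-7), and dynamic prediction accuracy that broadly rises with the
   number of observed reviews.

### Prevalence calibration

`calibrate_prevalence` measures each archetype's (PHQ, GAD) RI signature
on one-hot pilot cohorts, then solves the two-target mixing problem over
the archetype simplex by constrained least squares (SLSQP) with a small
(3e-4) ridge toward a plausible clinical prior mixture, and verifies the
solution on an independent pilot cohort. The shipped default weights are
the frozen output of this procedure: steady 0.570, sudden-gain 0.199,
late 0.231. Under the shipped conditions the feasible region contains
essentially no explicit non-responder mass — with 60% of clients exiting
at two reviews, steady improvers truncated early already supply the
label-negative population, so a separate non-responder archetype is
redundant at these targets. Calibration raises `CalibrationError`, with
the best achieved prevalences attached, when the targets are unreachable.

### What the generator does not model

No free-text or supporter behaviour, no demographic covariates, no real
content taxonomy (interaction types are anonymous integers), no
within-review-period temporal structure, and no instrument measurement
model beyond additive Gaussian noise on totals. Archetypes are a
five-shape mixture, far cleaner than real heterogeneity. Passing tests on
this cohort therefore demonstrate the correctness and statistical
behaviour of the pipeline — labeling, featurization, training, dynamic
evaluation — not clinical performance on any real population.

## Models

**Recurrent classifier.** A compact LSTM written in numpy: linear input
map (default projection 32), one LSTM layer with 50 hidden units, inverted
dropout 0.4 on the final hidden state, linear softmax over the two
classes. Trained many-to-one with minibatch Adam (lr 5e-3, batch 128) on
the cross-entropy loss. Every client contributes one training example per
observed prefix, all sharing the end-of-treatment label, so one model
answers at every review period; inputs are standardized by pooled training
moments. Model selection is by validation accuracy with early-stopping
patience 10. Backpropagation through time is hand-written and verified
against central finite differences in the test suite. Training is
deterministic given the seed.

**Static benchmarks.** Logistic regression, random forest, and gradient
boosting (scikit-learn) consume length-16 vectors: eight total-score slots
(zero where unobserved, avoiding imputation bias) plus eight availability
indicators. They are trained on all observed prefixes, like the sequence
model, so a single fit serves every prediction time.

**EMA baseline.** Exponential smoothing `s_1 = x_1`,
`s_k = α x_k + (1-α) s_{k-1}` with default α = 0.6 (configurable and
reported in outputs; the smoothing constant is a package default, not an
empirically fixed value). The one-step forecast stands in for the final
score: it is rounded to the nearest integer, clipped to the instrument
range, and passed through the RI criterion against the baselines. An
optional linear-trend extrapolation was considered and rejected as a
default in favour of the simpler, more conservative one-step proxy.

## Evaluation

Predictions exist only up to each client's last observed review — no model
ever consumes later measurements, and an audit test proves prefix
predictions are bit-identical under arbitrary modification of later
reviews. "All t" figures pool prediction time points (one evaluated
prediction per observed review per client); a per-client-averaged variant
is available. Sensitivity at fixed specificity picks the score threshold
attaining the smallest specificity at or above the target, breaking
specificity ties toward the higher sensitivity (the upper ROC envelope);
the degenerate all-negative point is not an operating point, so fully tied
scores are flagged unattainable rather than silently satisfied. Rates with
empty denominators are reported as not-applicable (NaN), never zero.
Bootstrap intervals resample whole clients (cluster bootstrap) to respect
within-client correlation of repeated predictions. Operating thresholds
can be selected on validation scores and applied frozen to test scores
(deployment mode) or computed on the reported set itself; outputs label
which mode produced them.

Time-to-improvement curves use the product-limit (Kaplan–Meier) estimator
(lifelines) on the first review opening an unbroken run of reliable
improvement through the last observed review ("sustained" improvement);
clients without such a run are censored at their last review.

## Error analysis

At a fixed prediction time (default t = 3) predictions are partitioned
into the four confusion cells, each member carrying its full trajectory
and true final change Δ. Mean trajectories average only clients observed
at each review index (ragged alignment, a package convention since
dropout makes lengths unequal). `threshold_proximity` reports the fraction
of members with Δ within a window of the RI threshold change (−6 PHQ-9,
−4 GAD-7); on noisy cohorts errors concentrate near the threshold relative
to correct predictions, and a test asserts exactly that comparison.

## Numerical and design choices

- Tie-break and degenerate-input conventions: probability vectors must sum
  to 1 within 1e-9; item allocation visits items in random order drawing
  each uniformly from its feasible range; trajectory rounding uses
  round-half-to-even before clipping.
- Stage seeds in the pipeline derive from sha256(global seed, stage name),
  so adding a stage never perturbs another stage's stream.
- The 70:20:10 split is stratified by the target instrument's label and
  raises on single-class inputs rather than degrading silently.
- The "three-layer" recurrent topology is read as input map → single LSTM
  layer → linear softmax; dropout sits on the LSTM output. Stacked
  recurrent layers are deliberately out of scope.
- Whether static benchmarks should see only the target instrument's totals
  is genuinely ambiguous; the default is target-only (input dimension 1
  for Q), with `include_both_totals` to widen to both instruments.
- Test and experiment problem sizes (cohorts of 600–5000 clients, LSTM
  epochs ≤ 40–150) are the package's chosen desk-scale defaults; all are
  configurable upward.

## Known limitations

Label noise from LOCF is reproduced, not corrected: clients dropping out
early are labeled from their last observation, so apparent accuracy at
early review periods partly reflects labels that are already determined by
visible data. The generator's dropout–improvement coupling and PHQ/GAD
noise correlation (0.6) are plausibility choices, documented defaults
rather than estimates of any real cohort. The EMA smoothing constant and
the moderate/severe band boundaries are conventions. External validation
against real service data is out of scope.
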