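# Methods

## The measured quantity

All analyses operate on *single-trial responses*: a unit's mean firing-rate
change (Hz) between the 40 s window after vomeronasal pump activation
(sympathetic-trunk stimulation at t = 0) and the 30 s window before it.
The stimulus reaches the nostril 20 s before pump activation, so the quiet
span [-30, -20) s provides the baseline-rate distribution for the
responsiveness screen. A dataset is a units x stimuli x trials array plus
stimulus metadata (secretion, donor strain, donor reproductive state,
dilution).

Units enter the decoding analyses if a two-group rank test (Kruskal-Wallis
with tie correction; the exact Wilcoxon rank-sum when the pooled sample has
<= 20 observations) finds their post-stimulation rates for at least one
stimulus to differ at alpha = 0.05 from their pre-application baseline rates
pooled across all stimuli. The screen is deliberately uncorrected across the
12 stimuli of a panel: it defines dataset membership, not a per-stimulus
inferential claim, and with 12 tests at alpha = 0.05 roughly 46 % of
unresponsive units would pass by chance (the test suite checks this analytic
false-positive rate).

Row normalization for display and for the representation index maps each
unit's mean responses affinely onto [-1, 1] (max exactly 1, min exactly -1).
Constant rows map to all-zero rather than being undefined, so the trait
index exists for them; a divide-by-max-|r| variant is available via
`normalize(..., mode="maxabs")` but is not the default.

## Decoding

A decoding task is a two-label map over training stimuli and a (possibly
different) map over test stimuli. For the diluted single-secretion designs
this yields, per decoded trait: 6 simple pairwise tasks, 12 reciprocal
cross-dilution generalization tests, 2 dilution-invariant tasks (one per
level of the other trait), their 2 reciprocal cross-trait generalizations,
and 1 general task over all 12 stimuli. For the undiluted multi-secretion
design: 3 per-secretion tasks, 6 cross-secretion generalizations, 1
across-secretions task.

Population vectors are assembled by drawing a stimulus for the requested
label and then, independently for every unit, one of that unit's trials for
the stimulus (with replacement). Labels are balanced. The classifier is the
classic online perceptron: zero-initialized weights and bias, hard threshold
(activation > 0 -> label 1, exact ties -> label 0), error-driven update
w <- w + (t - y)x, b <- b + (t - y), samples visited in a fresh random order
per epoch, at most 100 epochs, early stop on an error-free epoch. Training
uses 100 vectors, testing 100 independently drawn vectors; each cycle is
repeated 10 times and averaged, because sample order makes training slightly
non-deterministic. Classifier inputs are raw Hz rate changes, not the
normalized matrix.

Ensemble-size dependence comes from sequential removal of the unit with the
smallest mean absolute weight (cycle-mean of L2-normalized |w|; ties go to
the lower unit index), retraining at every size down to one unit. Because
this path need not end on the best individual unit, an exhaustive one-unit
sweep is reported alongside. The complementary probe removes the
*highest*-|weight| unit per stage and counts how many can be removed before
accuracy falls below the best-single-unit reference.

### Trial reuse and honest evaluation

With ~5 recorded repeats per stimulus, independently drawn train and test
vectors inevitably reuse the same trials. This protocol is kept as the
default because it is what recordings permit, but it has a measurable
consequence the package makes explicit: a classifier can exploit
trial-specific noise shared between train and test draws, so even a
population with *no* trait tuning decodes label-vs-stimulus partitions well
above chance (~0.74 under the default geometry). Two honest-evaluation modes
exist for calibration and simulation work: `run_cycles(..., test_table=...)`
draws test vectors from an independently simulated table, and
`holdout_trials=True` reserves one trial index per cycle for testing.
Generalization tests are unaffected, since their train and test stimuli are
disjoint and share no trials. Null-calibration tests use an independent test
table with 200 repeats per stimulus, under which each null test decision is
an exact fair coin and pooled binomial intervals are exact.

## Trait-representation index

For unit i and a two-group stimulus partition (G1, G2),
I_i = |sum_{s in G1} R_is - sum_{s in G2} R_is| on the normalized matrix;
the population index is the mean over units. Significance comes from 10,000
shuffles that independently permute each unit's row across stimuli —
removing trait dependence while preserving each unit's response-magnitude
statistics. The headline p-value uses the add-one estimator
(1 + #{null >= observed}) / (1 + n_shuffles), which cannot return 0; the raw
exceedance fraction is reported alongside and is what the exhaustive-
enumeration test compares against. PCA of the normalized matrix treats units
as observations and stimuli as mean-centered variables.

## Synthetic populations

The generator emulates the measured quantity directly: each unit has a
baseline rate (truncated normal, 4 +/- 2 Hz) and additive tuning effects in
Hz. Defaults are chosen once as study conditions:

| parameter | default | meaning |
|---|---|---|
| n_units | 92 | set-1 geometry (diluted vaginal secretions) |
| n_trials | 5 | typical repeats per stimulus |
| effect magnitudes | 2 Hz | strain / state / secretion tuning strength |
| fraction_tuned | 0.5 per factor | share of units carrying each effect |
| interaction_fraction | 0.5 | state-tuned units whose sign flips with strain |
| dilution_gain | L 0.5, M 1, H 2 | multiplicative gain on evoked effects |
| trial_noise_sd | 1 Hz | additive Gaussian trial-to-trial noise |

Tuned units get a random effect sign; effect magnitudes are constant rather
than drawn, and the strain x state interaction units are a *count-balanced*
half of the state-tuned units. Both choices are deliberate: they make the
net state signal carried into an untrained strain cancel exactly, so that a
state classifier trained within one strain generalizes at chance — the
structure the recordings show — while an explicitly general classifier can
still exploit the consistent (non-flipping) half. Per-unit Bernoulli flips
would leave a sqrt(n) residual and blur that contrast. Dilution acts as a
pure gain, so responses scale but never change sign with concentration.

Trial noise is additive Gaussian on the rate change; nothing in the source
analyses constrains the trial-noise family, so this is a stand-in chosen for
matching the analysis variable (a mean rate change). A piecewise-constant
Poisson spike-train option (baseline rate before t = 0, baseline + effect
after, clipped at 0) supports end-to-end testing of the quantification
stage; it makes no claim of temporal realism.

What the generator does *not* emulate — and hence what passing tests do not
establish about recordings: correlated noise across units, temporal response
shapes and latencies, concentration-dependent recruitment of distinct
populations (in the generator, cross-dilution generalization succeeds
because gain preserves response sign; in the recordings it largely fails),
session/animal structure, and non-Gaussian trial variability.

## Numerical and procedural choices

- All randomness flows through explicit `numpy.random.Generator` objects;
  identical seeds give bitwise-identical outputs.
- Removal ranking uses cycle-averaged L2-normalized |w| because raw
  perceptron weight scale depends on the update count of each cycle.
- Decision ties (activation exactly 0) go to label 0; ranking ties go to
  the lower unit index — both documented, both seed-stable.
- The SVM comparison uses the kernel (x.y + 1)^2 with box constraint C = 1
  (sklearn `SVC(kernel="poly", degree=2, gamma=1, coef0=1)`); the exact
  parameterization of the original analysis environment is unknown, so these
  are configurable.
- The greatest-removal reference uses the overall best single unit (not a
  per-cycle best).
- Kruskal-Wallis on two groups with all values tied returns p = 1 by
  convention (no rank information); fewer than two observations per group
  yields a missing p.
- Problem sizes in tests and in `scripts/acceptance.py` follow the study
  geometry (92 units, 12 stimuli, 5 trials, 10 cycles, 10,000 shuffles);
  calibration checks use 20-200 replicate populations with reduced cycle
  counts, with intervals computed from the decision counts actually run.

## Known limitations

- The perceptron has no pocket/averaging; on non-separable data its final
  weights are the last epoch's state, which adds cycle-to-cycle variance
  (this is faithful to the original trainer but worth knowing).
- Under trial reuse, best-single-unit references computed from few trials
  are upward-biased order statistics; fixtures probing removal behavior use
  more repeats so the reference estimates true accuracy.
- The MAT loader is mapping-driven (array name + dimension order) because
  published single-trial archives do not share a fixed layout; it validates
  trial counts against a plausibility bound to catch transposed mappings.
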