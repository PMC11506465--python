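# Methods

## Scope and data model

The package models a storage experiment: oysters held at a constant
temperature (4, 12, 20 or 28 °C) while a 10-channel MOS gas-sensor array
samples their headspace and laboratory indices (TVB-N, total plate
count, hardness, three sensory sub-scores) are measured at sparse
sampling nodes. The prediction target is the 3-level freshness grade
defined by the TVB-N thresholds (< 15 mg/100 g fresh, 15–25 sub-fresh,
> 25 decayed; boundary values fall in the sub-fresh class because the
outer ranges are stated strictly).

## Synthetic data generator

No raw sensor recordings are publicly available, so the generator
produces datasets with the statistical structure the analysis assumes.
Everything is driven by a latent spoilage clock `u = t / horizon` in
[0, 1], split by two boundaries `(b1, b2)` into fresh, sub-fresh and
decayed phases.

**Quality trajectories.** Each index is a monotone PCHIP interpolant of
`u` through phase-anchored knots. TVB-N is anchored to cross 15 mg/100 g
exactly at `b1` and 25 exactly at `b2`; TPC crosses 6.70/7.70 log CFU/g
at the same boundaries (so the two grading rules agree by construction —
both indices are read off one spoilage clock); hardness falls from 5 N
to 0.2 N and the sensory sub-scores from ~9.5 to ~2, their mean crossing
the 8- and 5-point cut-offs near the phase boundaries. Gaussian noise is
added at the sampling nodes with per-index scales proportional to the
voltage-noise knob `noise_sd` (25, 5, 5, 10, 10, 10 index units per volt
for TVB-N, TPC, hardness and the sensory scores), so `noise_sd = 0`
yields exactly monotone trajectories.

**Sensor channels.** Each channel's mean voltage is a baseline plus one
or two logistic (saturating) components of `u`. Midpoints are placed
relative to the phase boundaries to encode the chemical roles: the
alcohol-sensitive channel (S9) has its midpoint inside the fresh phase;
the amine-sensitive channels (S1, S2, S5, S10) rise inside the decayed
phase; a sharp sulfide component (width 0.05) appears on S1, S2 and S6
only near the end of decay; the alkane/refrigerant channels (S3, S4, S7,
S8) contribute weak, broad responses. Amplitudes span 0.15–1.8 V over
baselines of 0.35–0.6 V. Measurement noise is i.i.d. Gaussian
(`noise_sd`, default 0.02 V) plus a per-channel random-walk drift whose
accumulated standard deviation over the horizon is `drift_sd` (default
0.05 V) — the slow baseline wander typical of MOS sensors, which the
min–max normalization downstream has to absorb.

**Rows, labels, condition presets.** Rows are a uniform instantaneous
subsample of the horizon (midpoint rule), so label proportions track the
phase fractions to within 1/n; the cleaning/collection cycle of the
physical sampling protocol is not emulated, since no downstream stage
uses it and burst sampling would quantize the label proportions. Labels
grade the noise-free TVB-N trajectory at each row's time. Per-condition
presets: horizons 216/168/72/48 h, row counts 4200/4800/4200/7800, and
quality sampling nodes matching the laboratory protocol (6 nodes at
4 °C, daily at 12 °C, 12-hourly at 20 °C, 4-hourly at 28 °C). The class
boundaries per temperature — (0.42, 0.55), (0.26, 0.50), (0.31, 0.72),
(0.47, 0.77) — are set so the phase-duration fractions reproduce the
grade mix of the reference per-temperature test sets. Identical config
and seed give bit-identical output.

**What the generator does not emulate:** absolute voltage levels of real
sensors, cross-sensitivity to humidity/temperature excursions (both are
generated as constant-plus-noise and carried as metadata only), sensor
aging, and between-animal variability. Classifier accuracies measured on
this data therefore certify the pipeline's correctness and stability,
not field performance on real oysters.

## Chemometrics

Normalization is per-feature min–max to [0, 1] (the stored min/max are
reapplied to held-out data; constant features map to 0 with a warning).
PCA is computed by SVD of the centered (optionally standardized) matrix;
loadings are signed so each component's largest-magnitude entry is
positive, which makes outputs reproducible; the explained-variance ratio
is the squared singular values over their total. With the default
generator, three components retain ≥ 97% of the normalized 10-channel
variance (the calibration knob is the noise/drift level; the reference
range on real data is 96.4–98.5%). Shelf life for the correlation
analysis is remaining time to the decay deadline, the first timepoint
graded 3 by the TVB-N rule. k-means is a Lloyd iteration under the
Euclidean distance with seeded distinct-point initialization, an
explicit per-iteration inertia trace (nonincreasing by construction),
and farthest-point reseeding of emptied clusters. The loading-angle
analysis reports the sign of the dot product of two variables' 2-D
loading vectors; an exactly orthogonal pair is reported as positive.

## GA-BP classifier

Architecture: single hidden layer, sigmoid hidden and output units,
one-hot targets, argmax decision with ties broken toward the lower
grade. Defaults: 3 inputs (PCA scores), 10 hidden units, 3 outputs.

**Chromosome coding.** All parameters are flattened in the order
input→hidden weights (row-major), hidden biases, hidden→output weights,
output biases; encode/decode are exact inverses.

**Genetic algorithm.** Population 40, 100 generations, genes initialized
uniformly in [−1, 1] (normalized inputs keep activations in the
sigmoid's responsive region), roulette-wheel selection, elitism 1 (the
best-fitness trace is therefore nondecreasing), arithmetic blend
crossover with probability 0.8, per-gene Gaussian mutation (probability
0.05, s.d. 10% of the bound width, clipped to bounds). Fitness is
1/(1 + SSE) of the decoded, untrained network on the training set. The
GA's contribution is a good starting point: in paired-seed experiments
its chromosome starts backpropagation at a lower loss than a random
draw essentially always, and it avoids the rare initializations that
fall into a basin merging the sub-fresh and decayed classes. Final
training losses after full backpropagation are statistically
indistinguishable between GA and random starts on these data — the
adaptive optimizer equalizes them — so the package's tests assert the
starting-loss property rather than a final-loss one.

**Backpropagation.** Full-batch gradient descent on half the summed
squared output error (the same SSE as the GA fitness; a per-sample mean
gradient at the same settings trains orders of magnitude too slowly).
The step size adapts with the classical schedule: after an epoch whose
loss does not exceed 1.04× the previous loss the step grows by 1.05;
otherwise the step is rolled back and shrunk by 0.7. Initial rate 0.01,
2000 epochs. Plain fixed-step descent is available (`adaptive=False`)
but stalls on shallow plateaus for a minority of seeds; the adaptive
schedule removed every such failure in a 24-run seed×temperature sweep
(all held-out accuracies 95.4–99.2%).

**Evaluation.** Stratified 8:2 split (stratification prevents
empty-class test folds; a temporally blocked split is available via
`stratified=False` after sorting). Overall accuracy is 100×trace/total
of the 3×3 confusion matrix; per-class accuracy is class recall
(diagonal over row sum) — the only reading consistent with the
reference percentages — displayed at 4 and 1 decimals respectively,
with full precision kept internally.

## Numerical and design notes

* Sensory grading uses the unweighted mean of the three sub-scores.
* `quantify_dms` returns full precision; 3-significant-figure rounding
  is display-only.
* Dataset CSVs are written with 12 significant digits, so a write/read
  round trip is exact to well below the 1e-9 tolerance.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the pipeline derives per-stage seeds as small offsets from the
  master seed, and every report embeds the config hash and the seeds
  used.
* Problem sizes in the test suite are desk-scale (hundreds of rows,
  reduced GA budgets) except the acceptance experiment, which runs the
  full default sizes; the whole suite completes in about half a minute.

## Known limitations

* The generator's single-latent-clock design makes the classes almost
  perfectly separable along a 1-D manifold in PCA space; real e-nose
  data carry replicate-to-replicate and drift structure that would lower
  accuracy.
* The GA uses raw fitness-proportional selection; with large training
  SSE all fitnesses are small and selection pressure is weak, so the GA
  behaves partly as a seeded random search. Rank or tournament selection
  would strengthen it but is not what the modeled procedure specifies.
* Per-class recall is undefined (reported missing) for a grade absent
  from the test fold; stratified splitting avoids this by construction.
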