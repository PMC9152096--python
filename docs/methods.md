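# Methods

This note records the model, the procedure, the defaults and the numerical
conventions the package implements, and what its synthetic validation does
and does not establish.

## Functional-connectivity features

Input is a panel of per-subject ROI × time matrices. Each ROI series is
z-scored (mean 0, sd 1 over its own time points) and truncated to a uniform
length — by default the shortest series in the panel, counted from the first
sample. Standardisation makes downstream Pearson correlations invariant to
per-site affine distortions of the raw signal, which is exactly the class of
site effect the synthetic generator can inject; truncation point is a
convention (nothing in the correlation structure of the generator depends on
where the slice is taken, and for real data the slice start is a config
choice).

Feature (s, e) is the sample Pearson correlation between the two ROI series
of subject s for edge e. Edges enumerate the strict upper triangle of the
ROI × ROI matrix row-major, 0-based, i &lt; j: e = 0 ↔ (0, 1), and for
R = 90, e = 4004 ↔ (88, 89), E = 4,005. This bijection is fixed and shipped
alongside every feature table, because every frequency table and region
ranking depends on it being stable.

Degenerate inputs: a constant (zero-variance) series cannot be z-scored; it
is mapped to all zeros with a warning, and any correlation involving it is
defined as 0 (flagged) rather than NaN, keeping downstream linear algebra
total. Constancy is detected by exact max-minus-min equality, not `sd == 0`,
because a constant series stored in floating point has sd ≈ 1e-16.

The shipped AAL label table has 116 rows (index, short name, full name,
lobe, cerebellum flag); loading with the default filter drops the 26
cerebellar parcels and retains the 90 cerebral ones used for features.

## The random SVM cluster

Subjects are split into training S1, validation S2 and test S3 at 4:1:5,
stratified by class. Set totals come from largest-remainder apportionment of
the whole cohort; per-class counts are apportioned the same way constrained
to those totals, so every set preserves the patient/control proportion to
within one subject per class. For a 479/478 cohort this yields 383/96/478.
(Summaries of the emulated study print 382/96/479, which no standard
rounding of 957 at 4:1:5 produces; the package follows the arithmetic and
documents the difference here.)

Each of n members draws M subjects from S1 (default M = ⌈0.8·|S1|⌉ without
replacement — large enough to train on, small enough to decorrelate members;
bootstrap resampling is available by flag) and d of the E features without
replacement, then trains a support-vector classifier on that submatrix. The
base learner is a linear-kernel SVC with C = 1: correlation features are
near-linear problems, and a linear margin keeps the feature-frequency
interpretation clean (an RBF kernel is available by config). Draws that
miss one of the two classes are retried up to 100 times, then rejected with
the member index named.

Determinism: member m's random stream is `SeedSequence((seed, m))`, so the
fit is a pure function of (data, split, config, seed) and is independent of
execution order. Member sample and feature indices are sorted after drawing;
this is cosmetic for the ensemble but makes the degenerate configuration
n = 1, d = E, M = |S1| reproduce a single SVM trained on S1 in natural order
bit-for-bit.

Screening scores every member on S2 and deletes those with accuracy
*strictly below* 0.5 ("worse than guessing"); a member at exactly 0.5 —
common on balanced validation sets, where a constant predictor lands exactly
there — is retained. The surviving k members vote; a test subject is labelled
patient iff the vote fraction exceeds 0.5, with exact ties broken toward the
patient label (deterministic, and the sensible direction in a screening
context). The vote fraction is exposed as a score in [0, 1].

Evaluation reports accuracy, precision and recall with patient as the
positive class; if no subject is predicted positive, precision is reported
as 0 with a flag instead of NaN.

## Hyperparameter sweeps

n (member count) is swept first (default 5–600 step 5) at fixed d. Accuracy
rises and then plateaus; "started to be stable" is formalised as the first
grid point from which a trailing window of w = 5 accuracies has range
&lt; tol = 0.02 (both exposed). If no window qualifies, the grid maximum is
returned with a warning. d is then swept (default 70–300 step 2; 70 is the
conventional ~√E starting point for E = 4,005) at the selected n and chosen
by accuracy argmax, ties toward the smaller (cheaper) value. Sweeps share
one split across grid points so curves are comparable; repeats (default 5,
mean reported) re-randomise only member construction. Both selection rules
are pure functions of the accuracy curve and are unit-tested on synthetic
curves with forced answers.

## Region discovery

Members with validation accuracy *strictly above* 0.75 are the superior
classifiers. Validation (S2) accuracy feeds this threshold so that test
labels never influence feature discovery; a config switch allows a
test-accuracy reading for replication purposes. Edge frequency = number of
superior members whose feature subset contains the edge (total = k_sup · d
exactly). The k most frequent edges are the optimal features (k defaults to
the tuned d); boundary ties break by ascending edge index so outputs are
bit-stable. Each optimal edge increments both endpoint ROI weights
(Σ weights = 2k), and ROIs are ranked by weight, ties by index. The top
edges can be exported as a plain-text connectome edge list with node weights
for standard viewers.

## Benchmark harness and cohort statistics

`run_baselines` repeats (default 50×): draw a fresh stratified split, train
every requested method on it, score on the test set. All methods share the
split within a repeat, so comparisons are paired. Registered baselines: KNN
(k = 5), Gaussian naive Bayes, a single hidden-layer feedforward network
(32 units — the stand-in for product-based/backpropagation networks, which
are under-specified as published), a single linear SVM, and a random forest
(100 trees), all from scikit-learn; plus the random SVM cluster itself.
Scores (decision function, class-1 probability, or vote fraction) are pooled
across repeats for precision–recall curves.

The P-R curve sweeps the decision threshold over the unique score values
(predict positive at score ≥ threshold) and stops at the full-recall point —
lower thresholds only add false positives at recall 1. Output is sorted by
recall.

Cohort demographics are compared with Welch (unequal-variance) two-sample
t-tests — from raw values or directly from printed (mean, sd, n) group
summaries — and age with a chi-square test on binned values (default decade
bins, configurable), reported in "mean ± sd" form. From the emulated
cohort's published IQ summaries (n = 479/478), FIQ and VIQ give |t| ≈ 6.26
and 6.91, p rounding to 0.000 at three decimals; the PIQ summaries give
p ≈ 3·10⁻⁴, which also rounds to 0.000 rather than the printed 0.001 —
consistent with per-variable missing data in the source cohort. The package
reports what its inputs imply and does not attempt to resolve this.

## Synthetic cohorts: what they emulate, and what they do not

`generate_cohort` draws, per subject, independent unit-variance white-noise
series for every ROI, except that each planted edge (i, j) with group target
correlation r shares a latent factor: x = √(1−a²)·ε + a·s with a = √|r|
(negative targets negate the loading on one endpoint), giving population
correlation exactly r. Planted edges must be vertex-disjoint, which keeps
every non-planted pair at population correlation 0 and the construction
exact in O(R·T). Site effects are applied post hoc as affine transforms
(site m: x ↦ scale^m·x + shift·m), which by construction perturb only what
z-scoring must undo. Demographics are drawn independently of the series
(they describe the cohort; they are never features), defaulting to the
published group summaries (age 16.70 ± 8.23 / 17.20 ± 8.06, FIQ
105.21 ± 16.56 / 111.20 ± 12.80, PIQ 104.89 ± 17.06 / 108.61 ± 13.31,
VIQ 103.25 ± 18.05 / 110.37 ± 13.50).

What this does **not** emulate: autocorrelated BOLD dynamics, hemodynamic
response shape, head motion, global signal, spatially structured noise,
distributed weak effects across many edges, or correlated edge effects.
Consequently, passing the recovery tests shows the *procedure* (screening →
frequency ranking → region weights) correctly concentrates on
group-differential correlations when they exist; it does not certify
performance on real multi-site fMRI, where effects are weaker, denser and
correlated. Effect sizes are calibration choices, not published values: no
edge-level effect-size estimate for the real patient/control contrast is
available, so the strong-effect fixtures use Δr = 0.4 (0.1 → 0.5), chosen as
"comfortably detectable at T = 150" (sampling sd of r at T = 150 is ≈ 0.08,
so Δr = 0.4 is a ~5 sd edge-level separation).

## Validation conditions and problem sizes

The test suite and the acceptance script validate at desk scale, chosen so
each property is measured with adequate statistics:

- Null calibration: no-signal cohorts (r identical across groups), 60
  subjects/group, 90 ROIs, T = 120; clusters of 100 members at d = 60;
  mean screened-cluster test accuracy over 10 seeds must lie within
  0.5 ± 3 binomial SE.
- Planted recovery: 20 vertex-disjoint planted edges (0.1 → 0.5), 100
  subjects/group, T = 150, superior threshold 0.75, k = 20. The ensemble
  operating point for this fixture is n = 1,500 members at d = 20, frozen
  after a one-time calibration: recovery by frequency ranking requires the
  per-edge appearance counts of planted edges (≈ n·d/E) to clear the extreme
  order statistics of the ~4,000 background edges (≈ Poisson with mean
  n·q·d/E, q the chance a member holds any planted edge), which favours many
  members of low dimensionality. At this point mean top-20 precision and
  rank-40 ROI recall exceed the 0.8 floors. A smaller operating point
  (n = 200, d = 100) is also exercised in the acceptance tests; at that
  setting the count contrast (capped at 1/q ≈ 2.6) is insufficient and
  recovery precision sits near 0.2 — a structural property of
  frequency-ranking ensembles worth knowing when choosing n and d.
- Oracle equivalence: voting, feature counting and P-R computation are
  checked against brute-force re-implementations on 1,000 randomized small
  instances.

## Known limitations

- The feature-frequency statistic ranks edges by availability to accurate
  members; it has no significance calibration, and with few members or large
  d its background noise floor is high (see above).
- Majority voting is unweighted; accuracy-weighted voting and calibrated
  vote probabilities are out of scope by design.
- Atlas support is the shipped AAL table; other parcellations would need
  their own label tables.
- The pipeline starts from clean ROI time series; no image-level
  preprocessing is included or emulated.
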