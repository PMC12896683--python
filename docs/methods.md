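# Methods

This note documents the models, conventions, and design choices behind
`sldecode`: what the synthetic generator emulates, exactly how the decoding
pipeline is assembled, what the statistics assume, and where the open
design decisions were resolved.

## Data model and conventions

Epoched data live in an `EpochSet`: a `trials × sensors × samples` float
array, a uniformly spaced time axis in seconds, the sampling rate (default
200 Hz), and a trial table with one row per trial. Time 0 marks
placeholder-display onset and 1.5 s marks search-display onset; epochs
default to the span [−0.5, 2.5] s, which covers every analyzed window.

All time intervals are half-open `[t0, t1)`: a sample at time *t* belongs
iff `t0 ≤ t < t1`, computed in sample units with a small tolerance so
floating-point jitter on the grid cannot shift a boundary. This makes
sample counts unambiguous (e.g., [0, 1.5) at 200 Hz is exactly 300
samples).

Trial tables carry the condition labels (distractor presence, hemifield
and position; target hemifield and position; the session's
high-probability hemifield) and derived previous-trial (N−1) labels.
Previous-trial labels reset at block boundaries (first trial of each block
is NA); trials whose previous trial was distractor-absent are labelled
`absent` and are excluded from N−1 decoding, as are NA trials. The
container format is a plain HDF5 layout (`/data`, `/times`, `/sfreq`,
`/trial_table` as UTF-8 CSV bytes) with dataset timestamps disabled so
identical inputs produce byte-identical files.

## Synthetic data generator

The generator emulates the task's *design*, not MEG biophysics. It has two
parts.

**Design realization.** Probabilities are realized as exact counts
(rounded, then shuffled) rather than Bernoulli draws: per session of
`blocks × trials_per_block` trials (default 6 × 120 = 720),
`round(0.66·n)` trials are distractor-present; `round(0.75·n_present)` of
those fall in the session's high-probability hemifield (roles swap between
the two sessions); within each hemifield the two distractor positions are
split as evenly as integers allow; targets are independently assigned
exactly 50/50 across hemifields with positions balanced within hemifield.
Exact counts make design-level checks deterministic. The generator does
not model the geometric constraint that target and distractor cannot share
a display position; hemifield counts — the decoded quantity — are exact
either way.

**Signal model.** Each trial's data are a sum of condition-locked effects
plus noise:

```
data[trial] = Σ_effects  sign(label) · amplitude · envelope(t) · pattern + noise
```

where `sign` is ±1 for left/right of the effect's label column (0 for
absent/NA). The five effects and their defaults:

| effect          | label column              | window (s)      | amplitude |
|-----------------|---------------------------|-----------------|-----------|
| presearch       | distractor hemifield      | [0.1, 0.7]      | 0.4       |
| early reactive  | distractor hemifield      | [1.575, 1.625]  | 0.8       |
| late reactive   | distractor hemifield      | [1.675, 1.725]  | 0.8       |
| target (post)   | target hemifield          | [1.675, 1.725]  | 0.8       |
| carryover (N−1) | prev. distractor hemifield| [0.1, 0.7]      | 0.3       |

Amplitudes are in units of the noise SD. They are not calibrated to match
empirical decoding magnitudes (the real effect sizes are unknown); they
are chosen once so that the planted structure is recoverable with 20
simulated subjects at desk scale, which is the regime the recovery checks
operate in.

Envelopes are boxcars with half-Gaussian on/off ramps. The `ramp`
parameter (default 25 ms) is the full transition width, with Gaussian σ =
ramp/2; this keeps the early (~100 ms post-search) and late (~200 ms
post-search) windows, which are only 50 ms apart, effectively disjoint —
essential because the early-vs-late dissociation is the point of the
design.

**Patterns.** Effect patterns are unit-norm sensor vectors constructed in
the zero-mean subspace of sensor space (so Pearson correlation equals the
inner product) by Gram–Schmidt: requested pairwise correlations are exact
by construction, not sampled. Defaults: `corr(p_pre, p_late) = 0.8`
(shared proactive/reactive mechanism), `corr(p_pre, p_early) = 0` (early
sensory stage independent of the proactive code), `p_target ⊥ p_pre`.

`corr(p_pre, p_carryover) = 0.5` by default, and this choice deserves
explanation. Within a session the trial sequence is an exchangeable
shuffle, so the N−1 and N distractor labels are conditionally independent
given the session; the marginal tendency of consecutive distractors to
share a hemifield (0.75² + 0.25² = 0.625) is purely a consequence of the
shared biased marginal and is invisible to a session-wise decoder. A
carryover pattern orthogonal to the presearch pattern therefore *cannot*
produce prev→current transfer, no matter the label statistics — we
verified this empirically (transfer AUC ≈ 0.49). What does produce
transfer is representational overlap: if the intertrial trace occupies
partly the same sensor pattern as the proactive bias — which is exactly
the shared-mechanism account the analysis is designed to probe — then a
classifier trained on N−1 labels picks up a direction that also carries
current-trial presearch information. The 0.5 default encodes that overlap
at an intermediate strength; setting it to 0 (and carryover amplitude to
0) yields the transfer null.

**Noise.** Gaussian sensor noise with covariance `(1−c)·I + c·R`, where
`R` is a random unit-diagonal correlation matrix and `c` = 0.2 by default,
temporally smoothed by a moving average (20 ms) and rescaled so the
marginal SD stays at `sensor_sd` — the smoothing then only introduces
autocorrelation. The generator deliberately omits 1/f spectra, forward
models, and artifacts; passing recovery tests shows the *pipeline* is
correct and unbiased, not that real MEG effects of this size exist.

**Scales.** Full scale is 306 sensors and 720 trials/session; the desk
scale used throughout the tests is 64 sensors and 240 trials/session
(2 blocks of 120), 20 simulated subjects, which keeps the complete
simulation-plus-decoding suite in the tens of minutes on one CPU while
preserving every qualitative property of the design.

## Decoding pipeline

Per time center, features are the sensor values in a centered
`window_samples` window (default 5, i.e., 25 ms at 200 Hz), flattened
sensor-major. Centers whose window would leave the epoch are excluded
rather than padded (no fabricated samples; note the window induces up to
±10 ms temporal smearing). A `time_step` parameter strides the evaluated
centers (default 1 = every sample; desk-scale analyses use 4, a 20 ms
grid) without changing any per-center computation.

Order of operations per session (sessions are processed independently and
averaged within subject):

1. **Filtering** — rows whose relevant label is not left/right (absent,
   NA) are dropped.
2. **Balancing** — one seeded draw per session subsamples the majority
   class to the minority count. Already-balanced labels (targets, by
   design) are left untouched.
3. **Cross-validation** — stratified K-fold (default 5) over *raw trials*,
   shuffled with a session-derived seed. For label transfer, folds are
   stratified on the joint (train-label, test-label) combination when
   counts permit, so test folds retain both test classes.
4. **Pseudotrials** — within the training and test partitions separately,
   each class is randomly partitioned into groups of exactly `m` (default
   5); each pseudotrial is the group mean; remainders are dropped; no
   trial is used twice. The partition is drawn once per (fold, repeat) and
   reused across all time centers — required for coherent temporal
   generalization (the model trained at *t* must be evaluated on the same
   held-out pseudotrials at every *t′*) and substantially cheaper.
   `n_repeats` (default 1) redraws the partitions and averages the AUC.
5. **Standardization** — per-feature z-scoring with mean/SD estimated on
   training pseudotrials only. The SD uses the population convention
   (denominator *n*, matching scikit-learn's `StandardScaler`); features
   with zero training SD are mapped to 0 in both sets.
6. **Feature selection** (optional) — top-k one-way ANOVA F statistics,
   computed on the training set only (the F statistic is scale-invariant,
   so this commutes with standardization).
7. **Classifier** — linear SVM (`SVC(kernel="linear")`, C = 1 fixed; no
   hyperparameter tuning) for time courses; logistic regression for
   generalization analyses. Decision scores are oriented toward the
   lexicographically larger class.
8. **Scoring** — ROC AUC of held-out decision scores, computed as the
   tie-aware Mann–Whitney statistic; averaged over folds and repeats.

When a transfer fold's test side loses a class after pseudotrial grouping
(possible because test pseudotrials are grouped by a different label than
the one stratifying the folds), that fold/repeat is skipped with a warning
rather than failing; the pipeline errors only if every fold is lost. The
pipeline's transfer analysis caps the pseudotrial size at 2 because N−1
filtering plus balancing leaves few trials per test class at desk scale.

**Generalization.** The temporal generalization matrix fits a model per
train center within each CV fold and scores it at every test center
(scored via the model's raw-space effective weights, so standardization
and selection are folded in exactly). Cross-epoch curves align lags from
the two interval onsets: at lag τ, train at `pre_start + τ`, test at
`post_start + τ`, and vice versa; the lag grid steps by `time_step`
samples and lag 0 is the interval start. Label transfer trains on one
label column and scores the held-out pseudotrials against another; with
identical columns it reduces *exactly* (bit-for-bit) to plain decoding.

**Haufe patterns.** `A ∝ Cov(X)·w`, unit-normalized, sign fixed so
`⟨A, w⟩ ≥ 0`, with a tiny ridge on the covariance diagonal for degenerate
cases.

## Statistics

*Cluster-mass permutation tests.* Point-wise two-tailed one-sample *t*
tests against chance are thresholded at α = 0.05; supra-threshold points
are grouped by adjacency (1D: temporal neighbors; 2D: 4-connectivity on
the train × test lattice, so diagonal touches do not merge), separately by
sign; cluster mass is the summed *t*. The permutation unit is the subject:
under the null, each subject's deviation curve is symmetric about zero, so
the null distribution of the maximum |mass| is built from random sign
flips of subject deviations (a single two-tailed null covering both
signs). When `2^n ≤ B` the test enumerates all sign patterns exhaustively;
otherwise Monte-Carlo p-values use the (k+1)/(B+1) convention, so p is
never exactly 0. Sign-flipping the per-subject deviations is the standard
group-level equivalent of label randomization for a one-sample test
against chance; it is adopted here as a declared choice. Flipping a
subject's sign leaves second moments unchanged, which permits a fully
vectorized t-map computation over all permutations.

*Windowed tests.* Subject curves are averaged over closed 50 ms windows
(e.g., lag 100 ms = 75–125 ms, 11 samples at 5 ms spacing), tested with
two-tailed one-sample *t* tests, and BH-FDR corrected across the family of
all windows × directions tested in one call. JZS BF10 is reported
alongside.

*Bayes factor.* The one-sample JZS BF10 places a Cauchy(0, r) prior
(default r = √2/2) on the effect size; the marginal likelihood under H1 is
the noncentral-t density integrated over the prior, evaluated by
Gauss–Legendre quadrature (201 nodes by default) after the substitution
δ = r·tan(θ), which maps the prior to the uniform measure on
(−π/2, π/2). The result is stable to node doubling at < 1e−6 relative
change and matches adaptive quadrature. For the reported statistic
t = 2.08, n = 20 the exact value is 1.3618; the printed 1.354 is what one
obtains from the unrounded t, so agreement is to print-rounding accuracy
(likewise p = 0.0513 vs the printed 0.052).

## Pipeline and reproducibility

`run_pipeline` derives every stage's seed as a pure function (SHA-256) of
the master seed and the stage name; a rerun with the same config and seed
is bit-identical at the result-file level (CSV/JSON outputs carry no
timestamps, and the manifest records the config, its hash, all derived
seeds, and the package version). Plots are deliberately not produced;
results are machine-readable tables plus a text report that flags which
planted effects were recovered.

## Known limitations

* The generator's realism stops at the design level: no forward model,
  no 1/f background, no artifacts, no eye movements. Recovery results
  validate the analysis code, not empirical effect sizes.
* Single-subject AUC estimates are coarse at desk scale (few pseudotrials
  per test fold, especially after balancing to the 25% hemifield); all
  substantive claims are group-level.
* Only two-class (hemifield) decoding is implemented; four-location
  decoding, source-space analyses, and sensor-adjacency clustering are out
  of scope.
* The exhaustive permutation fallback is limited by 2^n; for n > ~20
  subjects the test is always Monte-Carlo.
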