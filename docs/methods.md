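# Methods

## The decoding problem

A subject in the scanner can answer a yes/no question without moving or
speaking by *performing one of two mental tasks*: counting down numbers
to signal "yes", or recalling positive autobiographical memories to
signal "no". The two tasks evoke distinguishable whole-brain BOLD
patterns, so a linear classifier trained on labeled task blocks can
label each individual scan of a later answer period, and a majority
vote over those labels retrieves the answer. This package implements
that pipeline end to end — experiment timing, BOLD simulation,
preprocessing, univariate feature selection, single-scan
classification, a balanced-block permutation test, and majority-vote
decoding — so every stage can be exercised and validated on synthetic
data with known ground truth.

## Paradigm

Training (day 1): eight runs alternating 32 s blocks of the two tasks
with 16 s rests, three cycles per run; TR = 2 s, three dummy lead-in
scans; 147 scans / 294 s per run. Decoding (day 2): five binary-answer
runs — six spoken statements per run; 12 s after statement onset a
prompt cues the subject to perform the answering task for 24 s, then
16 s rest; 159 scans / 318 s per run — plus three more alternating runs
used to measure cross-day generalization. Scan indexing is 0-based over
the whole run including dummies; scan *i* covers `[i·TR, (i+1)·TR)`, so
window arithmetic is exact. Block onsets are shifted by 4 s (two TRs)
before scans are labeled, to account for the hemodynamic delay.

Blocks whose start cue went unacknowledged are flagged in the schedule
(by the simulator, or by the `acknowledged` column of the events file);
the schedule layer never infers them. The classification branch applies
the strict screening rule — an unacknowledged block is dropped together
with the same-ordinal block of the other task in the same run — so the
training set stays exactly balanced; the GLM branch drops only the
unacknowledged block itself.

## Synthetic data generator

The forward model for each in-mask voxel v is

    y(v,t) = B · (1 + β_a(v)·x_a(t) + β_b(v)·x_b(t))
             + drift + global fluctuation + motion leakage + AR(1) noise

where `x_a`, `x_b` are the task boxcars convolved with a canonical
double-gamma HRF (response peak 6 s, undershoot peak 16 s, unit
dispersions, peak:undershoot 6:1, 32 s kernel, peak-normalized), and
B = 800 arbitrary BOLD units is the baseline. In binary-answer runs the
response window of each trial carries the boxcar of the task matching
the trial's true answer. Blocks generate signal whether or not their
cue was acknowledged — the button press, not the task, is what is
missing.

Ground truth is two partially overlapping Gaussian blobs (σ = 1.6
voxels) on a 12×12×8 grid with an ellipsoidal brain mask (~320 voxels):
one blob responds more to task A, the other to task B, so both directed
GLM contrasts have voxels to find. The default blob-peak amplitude is
1.2% fractional signal change, a typical cortical block-design
response. The grid is deliberately small so the full pipeline runs in
under a second; it is configurable up to scanner scale.

Noise components, with defaults (all amplitudes are fractions of
baseline):

| component | default | form |
|---|---|---|
| thermal noise `sigma` | 0.018 | stationary AR(1), lag-1 ρ = 0.3, per voxel |
| drift | 0.01 | one cosine period per run, random phase, per-voxel amplitude spread |
| global fluctuation | 0.005 | one shared AR(1) series added to all in-mask voxels |
| motion leakage | 0.004 | random per-voxel loadings on the six motion parameters |

Motion parameters are smoothed mean-reverting Gaussian walks
(stationary AR(1) steps, ρ = 0.4, then σ = 1 scan Gaussian smoothing).
A pure random walk was rejected by design: its 1/f² spectrum
concentrates power exactly in the task-alternation band (~0.01 Hz), so
nuisance regression against such regressors removes task variance by
chance correlation and differently in each run — an artifact of the
regressor *shape*, not amplitude. Mean-reverting series spread their
power across the spectrum; the regression then removes only what it
should. White-matter and CSF confound series are independent smoothed
noise (they appear in the confound table but not in the data; the
spheres the real pipeline samples have no synthetic analogue). The
global-signal confound column is the true in-mask mean of the simulated
data. Everything derives deterministically from one master seed via
spawned per-run seeds.

The defaults were calibrated once so the default-protocol
leave-one-run-out accuracy lands in the mid/high 80s (%), matching the
regime the method operates in on real data, and then frozen. What the
simulator does **not** emulate: cardiac/respiratory waveforms and their
aliasing, motion artifacts in k-space, spatial autocorrelation of
noise, between-day changes in the activation maps, or any spatial
anatomy. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's computations, not performance claims
about scanner data.

## Preprocessing (classification branch)

Per run, after discarding the three dummy scans: (1) OLS residualization
of every in-mask voxel against the confound table (six motion
parameters, wm/csf means, global signal) plus a session constant;
(2) the session-mean image is added back — residualization removes each
voxel's mean, and a zero-mean series cannot subsequently be scaled to a
grand mean of 100, so the add-back is what keeps every stated step
meaningful; (3) high-pass filtering by residualization against the
discrete-cosine basis with all components below 0.008 Hz (for a 288 s
run that is 4 regressors; the DCT convention rather than a Butterworth
filter, since only a cutoff is specified); (4) multiplicative scaling
of the session to a grand mean of 100 over in-mask voxels × scans.
Then, across all of a day's runs jointly, each voxel is z-scored with
mean and SD pooled over the entire day — day 2 pools the binary-answer
and alternating runs together. Out-of-mask voxels are never touched;
every step is logged in the run's provenance.

Rank-deficient nuisance matrices fall back to the pseudoinverse with a
warning; zero-variance voxels z-score to zero with a warning.

## GLM feature selection

The GLM branch starts from the raw runs (shared with nothing but the
simulator): dummies dropped, volumes smoothed with an 8 mm FWHM
separable Gaussian (constant/zero padding, kernel truncated at 6σ so
the discarded tail is < 1e-9). The run-concatenated design has
HRF-convolved 32 s boxcars at acknowledged block onsets for each task,
six motion regressors, one constant per run, and a per-run DCT set at
0.0078 Hz (the GLM branch's own cutoff, kept distinct from the
preprocessing cutoff of 0.008 Hz). Serial correlation is handled by a
single pooled AR(1) coefficient — estimated from the lag-1
autocorrelation of the OLS residuals pooled over voxels and runs —
followed by prewhitening via the differencing transform applied within
each run (each run's first row is dropped; differencing across run
boundaries would be wrong) and a refit. Pooling one ρ rather than
per-voxel values is a stability choice on small grids.

Directed contrasts (A−B and B−A) yield t maps; thresholds are one-sided
(matching each contrast's direction): p < 0.001 uncorrected ("P001") or
p < 0.05 Bonferroni-corrected over tested voxels ("FWE05" — Bonferroni
is conservative and fully specified, standing in for random-field
corrections that need spatial smoothness estimates out of scope here).
The union of the two surviving sets — disjoint by construction — is the
feature mask. Masks are computed separately from the odd runs
(1, 3, 5, 7) and even runs (2, 4, 6, 8); the odd-run mask selects
features for a classifier trained on the even runs and vice versa, so
feature selection never sees the training scans.

## Classification

Features are the in-mask voxels of each training scan, min-max scaled
to [-1, 1] per feature with the minimum and maximum taken from the
training set only; test data gets the same affine map and may fall
outside [-1, 1] (no clipping); a constant training feature maps to 0.
The classifier is the standard L2-regularized hinge-loss soft-margin
linear SVM with C = 1, solved by LIBSVM; a brute-force quadratic-program
oracle in the test suite checks the optimum to 1e-4 on a toy problem.
The positive class is task A / yes. Leave-one-run-out cross-validation
refits the scaler and classifier per fold; the pooled accuracy divides
the total correctly classified scans accumulated over folds by the
total scan count. Cross-day evaluation applies the day-1 classifier to
the day-2 alternating runs without refitting.

## Permutation test

Significance of the held-out single-scan accuracy (the 360
response-period scans by default) uses a balanced-block permutation
test, 5,000 iterations by default: each iteration permutes the class
labels at block granularity independently within each run — every scan
inherits its block's permuted label — which preserves the three
structures that make naive scan-level shuffling anticonservative under
hemodynamic autocorrelation: run membership, block membership, and
per-run class balance. The classifier is retrained on each permuted
labeling and scored on the same evaluation scans. The p value uses the
add-one estimator `(1 + #{null ≥ observed}) / (1 + n)`, so it is never
zero and is bounded below by 1/(n+1).

Numerics: the linear kernel does not depend on labels, so the Gram
matrix is computed once and reused across all permutations, and every
fit inside the test (observed and null alike, keeping the comparison
consistent) uses a solver tolerance of 1e-2 — label-shuffled problems
converge slowly under LIBSVM's default tolerance, and the null accuracy
distribution is unchanged at this precision (mean/SD agree to < 1e-3).

## Decoding and scoring

Each trial's response window contributes the 12 scans starting at
(prompt onset + 4 s)/TR, anchored at the prompt (the window in which
the subject executes the answering task). Scans are scaled with the
*training* scaler and labeled by the sign of the decision value; an
exact zero is labeled +1 — with continuous features this is
measure-zero, but the rule must be deterministic. The answer is the
majority label over the first k scans, k odd (default 11 of 12), so a
tie is impossible; even k is rejected outright rather than tie-broken.
Scoring against the ground-truth key (which decoding never reads)
reports correct sentences per run, their mean ± SD, and the number of
sentences correct in *every* run. The duration-effect analysis
recomputes votes from the stored per-scan labels at k = 3, 5, 7, 9, 11
without re-classifying anything.

One property worth understanding when reading test expectations: even
with zero noise, the first scan of a shifted window is not guaranteed
the right label. Day-level z-scoring centers each voxel on its day
mean, and 4 s after the prompt the HRF is still ramping, so that scan's
activation sits below the mean and is intrinsically ambiguous — the
same early-window errors visible in real decision-value timecourses.
Noiseless simulations therefore decode 6/6 answers in every run with
high (but not perfect) single-scan accuracy.

## Problem sizes in the test suite

The suite favors the full default protocol (16 runs, 12×12×8 grid,
~320 mask voxels) where a single run suffices, and scales replicated
checks down: permutation-null calibration uses 20 zero-effect datasets
(4 training runs, 2 binary runs, 10×10×6 grid) × 200 permutations; the
duration-curve monotonicity property uses 20 seeds at reduced run
counts; the zero-effect cross-validation check uses the full 768-scan
training set. The acceptance script runs the complete default protocol
with the full 5,000-iteration permutation test.

## Known limitations

- FWE control is Bonferroni, which is more conservative than
  random-field or permutation-based voxel-level corrections.
- One pooled AR(1) coefficient serves all voxels; heteroscedastic
  serial correlation is not modeled.
- The simulator's noise is spatially white; real BOLD noise is
  spatially correlated, which would reduce the effective number of
  independent features.
- The split-half GLM masks assume an even number of training runs.
- Cross-day generalization in the synthetic world is optimistic: the
  planted maps are identical on both days by construction.
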