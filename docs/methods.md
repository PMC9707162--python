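# Methods

This note documents the models the package implements, the defaults it
ships, the synthetic data it validates against, and the numerical choices
made where the design was genuinely open.

## Paradigm and psychometric model

The task has a calibration phase and a testing phase. Calibration presents
a 50 ms target at 25 opacity levels spanning 0.01–0.25 (step 0.01 — the
only uniform step that yields 25 values over that range) in each of 8
screen positions (4 quadrant, 4 central), twice per position: 400 stimuli,
200 per location set, at 1–1.5 s jittered intervals. Detection responses
per location set are fitted by maximum likelihood with a logistic
psychometric function with lapse and guess rates,

    P(seen | x) = γ + (1 − γ − λ) · logistic(β (x − θ)),

and the threshold is θ, the 50% point of the lapse/guess-corrected curve.
The fit uses bounded L-BFGS-B with 5 restarts (θ within the data range ±
one range-width, β ∈ [1, 2000], γ, λ ∈ [0, 0.1]); all-seen or all-unseen
data return a non-converged fit clamped to the nearer range edge. Whether
the original sigmoid carried lapse/guess terms is an open choice; including
them costs ~0.3 percentage points of threshold bias on a 400-trial
calibration (measured by simulation) but is robust to real observers'
lapses, so they stay in by default.

Testing-phase trials have six phases (pre-stimulus, first stimulus,
inter-stimulus, second stimulus, post-stimulus, response) with 6–10 s
jitter on the waiting phases and a 2–4 s self-paced response phase. The
two stimuli of a trial fall in complementary location sets (first set
chosen equiprobably); each presentation is blank (12.5%), threshold (75%),
or fully opaque (12.5%), the opaque condition existing to measure false
negatives. Stimuli in the session's task-relevant set are "report"; the
others "no-report". The perceived label for report trials is the "yes"
answer to the perception question; location accuracy is tracked separately
(seen answers use the true location, unseen answers a uniform guess).

## Eye dynamics: generative model and processing

The generator emulates a video eye tracker at 250 Hz (a deliberate
desk-scale choice; the processing chain is sampling-rate agnostic and the
epoching test also exercises 1000 Hz). Pupil baseline is 1000 a.u. with
two noise components: white noise (SD 10 a.u.) and a slow drift formed by
a 2-s moving average of white noise scaled to SD 30 a.u. The drift is what
makes single-trial classification genuinely hard — with white noise alone,
window averaging would make the task trivially easy in a way real
pupillometry never is.

A consciously perceived stimulus adds:

- a pupil impulse response — gamma kernel (shape 2) normalized to unit
  peak, amplitude 40 a.u., peak latency 1.2 s;
- a blink-rate multiplication ×2.0 inside 0.5–2 s post-stimulus on a base
  Poisson rate of 0.3 events/s (blinks rendered as 100–300 ms invalid,
  zeroed pupil runs);
- a microsaccade-rate multiplication ×0.3 inside 0–1 s post-stimulus on a
  base Poisson rate of 1.0 events/s (microsaccades rendered as 0.1–0.5°
  ballistic gaze steps over 20 ms with a smooth half-cosine profile and a
  drift back toward fixation when eccentric).

Both point processes are sampled by thinning, so realized counts follow
the integrated rate exactly. These amplitudes are plausibility choices at
the scale of published threshold-perception pupillometry; they are *not*
empirical estimates, and the package makes no claim that they match any
particular dataset.

Processing mirrors the standard four-stream extraction: (1) blink
detection as maximal invalid/zero-pupil runs ≥ 30 ms, padded by 100 ms and
merged across < 100 ms gaps; (2) linear interpolation of pupil and gaze
across padded blinks (edge blinks filled with the nearest valid value; the
pre-interpolation mask is kept in `info['artifact_valid']`); (3)
microsaccade detection by the velocity-threshold method: 5-sample
moving-average velocity, per-axis median-based SD estimates, elliptic
criterion at λ = 6, minimum duration 6 ms — the standard algorithm for
this hardware class; (4) 12-s epochs, half-open [−6, +6) s around the
anchor, pupil baseline-subtracted over [−0.5, 0) s.

Interstimulus-interval (ISI) anchors sit at the arithmetic midpoint of
each interval between consecutive presentation onsets, kept only when the
interval can contain a full epoch. In the testing schedule this admits the
between-trial gaps (≳14 s) and excludes the within-trial gaps (6–10 s).
Optional injected "arousal events" add the perceived-stimulus pupil
template and extra blinks at the perceived blink rate, emulating
spontaneous awareness fluctuations without a stimulus; injected events do
not retroactively thin already-rendered microsaccades, a documented
simplification.

## Covert classifier

Features per epoch: pupil means over (0,1], (1,2], (2,3] s of the
baseline-corrected trace, pupil peak and peak latency over (0,4] s, blink
counts over (0,1], (1,2] s, and microsaccade counts over (0,0.5],
(0.5,1] s, the counts minus the epoch's own pre-anchor baseline rate
scaled to the window width. All-invalid epochs yield a flagged NaN vector,
never silent zeros. Training z-scales on the training set, screens to the
top-k (default 6) features by absolute two-sample t (identical duplicate
columns deduplicated, ties to the lower index), and fits an L2-regularized
logistic regression; the signed decision function is the score and 0 the
label boundary (score exactly 0 → not perceived). The same frozen pipeline
classifies no-report and ISI epochs. Single-modality ISI sorting uses a
median split on pupil mean (0,2] s, blink count (0,2] s, or microsaccade
count (0,1] s, with ties and the odd element going to the low set.

The exact feature set, selector, fusion rule, and classifier family are
declared substitutes chosen for interpretability (a 0-centered linear
score), not reconstructions of any particular implementation.

## Cluster-based permutation tests

For participant-level condition-difference data (timecourses or
space × time maps) the test computes a one-sample t at each point
(zero-variance points get t = 0 with a warning), forms clusters of
like-signed points with |t| above the two-tailed p < 0.05 threshold at
df = N−1, scores each cluster by its mass (sum of member t values; cluster
size is available as a config option), and builds the null as the maximum
absolute cluster statistic per sign-flip permutation, pooling signs for
two-tailed family-wise control. Sampled nulls use
p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never 0 and the test
is exact-or-conservative; when 2^N ≤ n_perm the full flip set is
enumerated instead. Adjacency is temporal-only (runs within each signal)
or spatiotemporal: 6-connected voxel grids via labeled connected
components, or an explicit symmetric channel neighbor graph (the small
synthetic montage uses a chain; real montages should supply their own).
Monte-Carlo calibration in the test suite puts the empirical family-wise
error at the nominal 0.05 (e.g. 0.055 ± 0.007 over 1000 null replicates at
n_perm = 1000).

Rank-sum comparisons use exact enumeration for combined n ≤ 12 without
ties and the tie-corrected normal approximation otherwise; all-tied inputs
return p = 1 by convention. Holm–Bonferroni adjustment is the standard
step-down procedure.

## ERP analyses

EEG epochs span [−0.5, +1.5] s at 250 Hz with baseline [−0.2, 0) s.
Component windows: N100 75–125 ms, VAN 175–225 ms, P2/N2 275–325 ms
(polarity disambiguates the shared window), P3 350–650 ms. The synthetic
templates make N100 stimulus-driven (present for all stimuli), VAN
perception-dependent but report-independent, and N2/P3 dependent on both
perception and overt report — so the perceived-minus-not contrast under
the no-report generator produces a VAN-window cluster and no P3 cluster,
while the report-minus-no-report contrast produces only late clusters.
The thalamic awareness potential template is a difference of two gamma
kernels, zero before its 250 ms onset with the negative phase beginning at
the 430 ms first peak, so the positive extremum falls exactly at the
nominal latency. Peak detection reports the signed extremum in a search
window (TAP window 0.25–0.65 s), ties to the earliest sample, and flags
extrema on a window edge. Latency comparisons run two-sided rank-sum tests
of each component against a reference (TAP) with Holm correction over the
family.

## BOLD analyses

Percent change is 100 · (signal − baseline mean)/baseline mean per voxel
per epoch, baseline [−2, 0) s before the event (a choice; it is not
specified by the design), epochs −20…+20 s on the TR = 1 s grid; voxels
with a non-positive baseline are masked out with a warning. Group
contrasts feed participant-level difference epochs to the spatiotemporal
cluster test. Conjunction keeps voxel-time points significant with the
same sign in both sources; exclusive disjunction keeps points significant
in exactly one; both operate at the voxel-time level with an
epoch-collapsed (any-sample) summary also exposed, since a voxel-level
definition is the natural alternative reading. Eye-movement-signal removal
tests, per modality, the paired contrast of no-report difference epochs
minus the modality-sorted difference epochs, and intersects the three
no-report-greater significance masks with the no-report mask itself — the
output is therefore always a subset of the no-report map, effects fully
explained by a single eye-movement modality cancel and drop out, and
isolated chance points can survive only by adjacency to genuine clusters.

Network partitioning selects voxels significant at ≥1 sample in (0, 10] s
post-stimulus and clusters their across-participant mean difference
timecourses with k-means, k = 3, distance 1 − Pearson correlation
(implemented exactly as Euclidean k-means on row-standardized
timecourses), best of 100 seeded restarts. Cluster labels follow the
dynamics rule: negative-dominated trough → DMN, positive peak ≤ 4 s → DAS,
later positive peak → TPN; the rule is defined only for k = 3 (other k
report unlabeled clusters). The synthetic templates put the DAS peak in
the 3–4 s bin, the TPN peak at ~6 s, and the DMN trough in the 6–8 s bin
on a 20×20×12 integer-labeled grid — no real anatomy, no MNI coordinates.

## Synthetic data: what it does and does not show

The generators reproduce the *structure* of the study's data — schedule
counts and probabilities, sigmoidal detection, perception-locked eye
dynamics, report-dependent late ERP components, three BOLD networks with
distinct timecourses, run lengths (a report-paradigm testing run is 720
volumes at TR 1 s) — under explicit, seeded models. They deliberately omit
head models and realistic EEG topography, hemodynamic response variability
across regions, scanner noise spectra, binocular geometry, and real
anatomy. Tests passing on this data demonstrate that the analysis chain is
correct and calibrated (it recovers known effects at generated effect
sizes and controls false positives on nulls); they do not certify
performance figures on real recordings.

Noise scales: EEG channel noise SD 5–8 µV per sample; BOLD epoch-average
noise SD 0.4% against network amplitudes 0.6–0.8% (participant-level SNR
2), with per-participant multiplicative amplitude variability (SD 0.15–0.2,
floored at 0.2). Network recovery is evaluated on across-participant
(N = 20) averages, matching how the clustering is actually run.

## Problem sizes and statistical estimators

Simulation sizes ship at desk scale: classifier validation uses 300
trials and a closed-form Bayes-rate oracle (Gaussian window-mean features
with the exact white+drift covariance, Poisson count features) as the
reference; permutation-test calibration uses 200–400 null replicates with
1000 permutations (temporal) and 500 permutations on the 10×10×5×20 grid
(spatiotemporal); ERP and fMRI generator-loop checks use 12–20
participants. The threshold hit-rate quantity is reported as the mean over
8 independent calibrate→fit→evaluate cycles of 2000 fresh responses each:
a single 400-trial calibration determines the 50% point's detection
probability only to ~4 percentage points (the Fisher-information limit of
the 25-level design), so the replicate mean is the estimator that actually
addresses the "≈50%" claim rather than re-measuring one calibration's
sampling error.

## Known limitations

- Monocular only; binocular averaging is not implemented.
- The eye-dynamics amplitudes are plausibility defaults, not fitted to any
  dataset; absolute classifier accuracies on real data will differ.
- Graph-adjacency cluster formation is quadratic in the worst case for
  dense supra-threshold maps; grids use `scipy.ndimage.label` and are fast.
- The ISI arousal injection adds pupil and blink signatures but leaves
  already-sampled microsaccades untouched.
- k-means labels depend on the dynamics rule; degenerate data where two
  clusters share a shape class produce a warning and repeated labels.
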