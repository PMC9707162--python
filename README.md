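# noreport

Analysis tools for studying **conscious visual perception without overt
report**, with a complete seeded synthetic-data module for development and
validation.

## The scientific problem

When participants report whether they perceived a stimulus, the report
itself contaminates the neural signal: decision-making, working memory, and
motor preparation all follow perception and are easily mistaken for it. A
*no-report paradigm* sidesteps this by presenting physically identical
stimuli that require no response and inferring perception covertly. Here
the covert channel is the eyes: consciously perceived stimuli at the
perceptual threshold produce a transient **pupil dilation**, a **blink-rate
increase**, and a **microsaccade-rate decrease**, and a classifier trained
on overtly reported trials can label unreported ones.

The package implements the full analysis chain around that idea, for
researchers working with threshold perception tasks, pupillometry/eye
tracking, EEG, and event-related fMRI:

- **paradigm** — two-phase task construction and behavior. Calibration
  presents a 50 ms face at 25 opacity levels (0.01–0.25, step 0.01) in 8
  locations, twice each (400 stimuli); detection responses are fitted with
  a logistic psychometric function
  `P(seen) = γ + (1 − γ − λ) / (1 + exp(−β(x − θ)))`, and the threshold θ
  (the 50% point) feeds the testing phase: runs of 24 six-phase trials with
  6–10 s jitter, two stimuli per trial in complementary location sets,
  drawn blank / threshold / opaque with probabilities 0.125 / 0.75 / 0.125.
- **eyeproc** — blink detection from invalid pupil runs, artifact
  interpolation, velocity-threshold microsaccade detection (median-based
  noise scaling, λ = 6), 12-s epochs (±6 s around an anchor), and
  event-rate timecourses.
- **classify** — the covert perception classifier: windowed pupil / blink /
  microsaccade features, z-scaling, t-statistic screening, feature-level
  fusion, and a regularized linear model whose signed decision score is
  thresholded at 0. Trained on report trials, applied unchanged to
  no-report and stimulus-free interstimulus-interval (ISI) epochs; epochs
  can also be median-split on a single modality.
- **clusterstat** — model-free cluster-based permutation tests. Point-level
  one-sample t maps across participants, clusters formed by temporal-only
  or spatiotemporal adjacency, cluster **mass** (Σt) against a max-statistic
  sign-flip null; exact enumeration when 2^N ≤ n_perm. Wilcoxon rank-sum
  (exact for small samples) and Holm–Bonferroni utilities.
- **erp** — component window means (N100 75–125 ms, VAN 175–225 ms, P2/N2
  275–325 ms, P3 350–650 ms), peak latencies including the biphasic
  **thalamic awareness potential** (onset ~250 ms, first peak ~430 ms),
  rank-sum latency comparisons, and channels × time cluster contrasts.
- **fmri** — percent-change BOLD epochs
  (`100 · (signal − baseline) / baseline`), spatiotemporal group contrasts,
  voxel-level conjunction / exclusive-disjunction maps, eye-movement-signal
  removal by three-way conjunction against pupil/blink/microsaccade-sorted
  contrasts, and temporal-correlation k-means partitioning of significant
  voxels into three networks: **DAS** (detection/arousal/salience, peak
  3–4 s), **TPN** (task-positive, peak ~6 s), **DMN** (default mode, trough
  6–8 s).
- **synth** — seeded generators for every input above: psychometric
  observers, eye sessions (gamma-kernel pupil response, Poisson blink /
  microsaccade point processes with perception-locked modulation), EEG
  epochs with report- and perception-dependent components, BOLD sessions on
  a labeled 20×20×12 voxel grid, and ISI segments with optional injected
  arousal transients.

A thin CLI (`noreport all --out DIR [--config run.yaml] [--seed N]`) runs
simulate → calibrate → classify → erp → fmri end-to-end, writing TSV / HDF5
/ NIfTI / JSON artifacts and a manifest of content hashes that reproduces
exactly under a fixed seed.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/01_calibration_and_threshold.py
calibration schedule: 400 stimuli (200 per location set)
quadrant: threshold opacity 0.101 (true 0.100), slope 37, converged=True
 central: threshold opacity 0.093 (true 0.100), slope 47, converged=True
hit rate at estimated threshold: 46.6% (a well-calibrated threshold sits near 50%)
```

The fitted thresholds recover the simulated observer's 0.10 to within the
design's resolution, and fresh stimuli shown at the estimated threshold are
detected near 50% — the defining property of a perceptual threshold.

```bash
$ python examples/05_fmri_networks.py
2 significant spatiotemporal clusters on the (20, 20, 12) grid
TPN: 194 voxels, peak at 6 s (+0.48% signal change)
DMN: 188 voxels, trough at 7 s (-0.49% signal change)
DAS: 177 voxels, peak at 4 s (+0.69% signal change)
ROI inside the DAS mask -> network fractions: DAS 100%, TPN 0%, DMN 0%
```

The data-driven partition recovers the three generated networks and their
timecourse shapes purely from the BOLD dynamics.

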