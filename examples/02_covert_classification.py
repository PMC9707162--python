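"""Covert perception classification from eye measurements.

Simulates an eye-tracking session where half the stimuli are consciously
perceived (pupil dilation, blink-rate increase, microsaccade suppression),
runs the processing chain (blink detection -> artifact interpolation ->
microsaccade detection -> 12-s epochs), trains the linear classifier on the
"report" half, and classifies the held-out "no-report" half covertly.
"""
import numpy as np

from noreport import classify as clf
from noreport import eyeproc
from noreport import paradigm as pg
from noreport.synth import generate_eye_session

rng = np.random.default_rng(0)
n_trials = 200
schedule = [
    pg.StimulusEvent(onset=10.0 + 16.0 * i, location_set="quadrant",
                     location=1 + i % 4, opacity_condition="threshold",
                     opacity=0.1)
    for i in range(n_trials)
]
labels = rng.random(n_trials) < 0.5
rec = generate_eye_session(schedule, labels, seed=1)

blinks, _ = eyeproc.detect_blinks(rec)
interp = eyeproc.interpolate_artifacts(rec, blinks)
msaccs = eyeproc.detect_microsaccades(interp, exclude_mask=interp.info["artifact_valid"])
epochs = eyeproc.epoch_eye(
    interp, [e.onset for e in schedule],
    blink_times=[b[0] for b in blinks], msacc_times=[m.onset for m in msaccs],
)
print(f"{len(blinks)} blinks and {len(msaccs)} microsaccades detected; "
      f"{len(epochs)} epochs of 12 s")

X = clf.feature_matrix(epochs)
half = n_trials // 2
pipeline = clf.train_pipeline(X[:half], labels[:half], seed=2)
outputs = clf.classify(pipeline, X[half:])
pred = np.array([o.label == "perceived" for o in outputs])
truth = labels[half:]
balanced = 0.5 * (pred[truth].mean() + (~pred[~truth]).mean())
print(f"held-out balanced accuracy: {balanced:.2f} "
      "(0.5 = chance; single-trial eye features are informative but noisy)")
print(f"example scores: {[round(o.score, 2) for o in outputs[:5]]} "
      "(score > 0 -> classified perceived)")
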