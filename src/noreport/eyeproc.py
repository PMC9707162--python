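"""Eye-tracking signal processing.

Extracts the four data streams used for covert perception measurement from a
pupillometry/gaze recording: artifact-interpolated pupil diameter,
artifact-interpolated gaze position, blink occurrence, and microsaccade
occurrence; then crops 12-s epochs (6 s pre / 6 s post an anchor) and builds
event-rate timecourses.

Blinks are detected as runs of invalid (zeroed) pupil samples, padded and
merged; microsaccades with a velocity-threshold detector whose noise scale
is a median-based estimate of the gaze velocity SD (elliptic criterion over
horizontal and vertical velocity), the standard approach for video-based
eye trackers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clusterstat

__all__ = [
    "EyeRecording",
    "EyeEpoch",
    "RateTimecourse",
    "MicrosaccadeEvent",
    "detect_blinks",
    "interpolate_artifacts",
    "detect_microsaccades",
    "epoch_eye",
    "event_rate_timecourse",
    "compare_eye_timecourses",
]

log = logging.getLogger(__name__)


@dataclass
class EyeRecording:
    """Uniformly sampled monocular eye data (pupil in arbitrary EyeLink-style
    units, gaze in degrees of visual angle)."""

    time: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("pupil", "gaze_x", "gaze_y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("stream lengths differ")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def duration(self) -> float:
        return len(self.time) / self.sampling_rate

    def copy(self) -> "EyeRecording":
        return EyeRecording(
            self.time.copy(), self.pupil.copy(), self.gaze_x.copy(),
            self.gaze_y.copy(), self.valid.copy(), self.sampling_rate,
            dict(self.info),
        )


@dataclass
class EyeEpoch:
    """A 12-s window around an anchor: baseline-corrected pupil plus blink
    and microsaccade event times expressed relative to the anchor."""

    anchor: float
    times: np.ndarray  # relative, half-open [-half, +half)
    pupil_corrected: np.ndarray
    blink_times: np.ndarray
    msacc_times: np.ndarray
    valid_fraction: float = 1.0

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) + (
            self.times[1] - self.times[0]
        )


@dataclass
class RateTimecourse:
    bin_centers: np.ndarray
    rate: np.ndarray  # events/s, pooled over trials
    n_trials: int
    sem: np.ndarray  # across-trial SEM per bin


@dataclass
class MicrosaccadeEvent:
    onset: float
    offset: float
    amplitude: float  # deg
    peak_velocity: float  # deg/s


# ---------------------------------------------------------------------------
# blink detection and artifact interpolation


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) half-open sample indices."""
    d = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_blinks(
    rec: EyeRecording,
    min_dur: float = 0.030,
    pad: float = 0.100,
    merge_gap: float = 0.100,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Blink intervals from invalid / zeroed pupil runs.

    Runs of invalid-or-zero pupil lasting at least ``min_dur`` become blinks,
    padded by ``pad`` on each side and merged when separated by less than
    ``merge_gap``.  Returns (intervals in seconds, boolean validity mask with
    padded blinks marked invalid).
    """
    fs = rec.sampling_rate
    bad = (~rec.valid) | (rec.pupil <= 0)
    if bad.all():
        raise ValueError("unusable recording: entire pupil trace invalid")
    min_samples = max(1, int(round(min_dur * fs)))
    intervals = []
    for start, stop in _runs(bad):
        if stop - start >= min_samples:
            intervals.append((start / fs - pad, stop / fs + pad))
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = [(max(0.0, lo), min(rec.duration, hi)) for lo, hi in merged]
    mask = rec.valid.copy()
    for lo, hi in out:
        mask[int(np.floor(lo * fs)) : int(np.ceil(hi * fs))] = False
    return out, mask


def interpolate_artifacts(
    rec: EyeRecording, blinks: list[tuple[float, float]]
) -> EyeRecording:
    """Linearly interpolate pupil and gaze across padded blink intervals.

    Intervals touching a recording edge are filled with the nearest valid
    value.  The pre-interpolation validity mask is preserved in
    ``info['artifact_valid']`` so downstream exclusion decisions can still
    see where artifacts were; the output's ``valid`` flags are all True (the
    trace contains no invalid-coded values after interpolation).
    """
    out = rec.copy()
    fs = rec.sampling_rate
    n = len(rec.time)
    bad = np.zeros(n, dtype=bool)
    for lo, hi in blinks:
        if not (0 <= lo and hi <= rec.duration + 1.0 / fs):
            raise ValueError("blink interval outside recording")
        bad[int(np.floor(lo * fs)) : int(np.ceil(hi * fs))] = True
    bad |= (~rec.valid) | (rec.pupil <= 0)
    if bad.all():
        raise ValueError("unusable recording: nothing to interpolate from")
    good_idx = np.flatnonzero(~bad)
    idx = np.arange(n)
    for name in ("pupil", "gaze_x", "gaze_y"):
        sig = getattr(out, name)
        sig[bad] = np.interp(idx[bad], good_idx, sig[good_idx])
    out.info["artifact_valid"] = ~bad
    out.valid = np.ones(n, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# microsaccades


def detect_microsaccades(
    rec: EyeRecording,
    lambda_thresh: float = 6.0,
    min_dur: float = 0.006,
    smooth_samples: int = 5,
    exclude_mask: np.ndarray | None = None,
) -> list[MicrosaccadeEvent]:
    """Velocity-threshold microsaccade detection.

    Gaze velocity is computed by central differences and smoothed with a
    ``smooth_samples``-point moving average.  A median-based SD estimate
    sigma_x, sigma_y sets an elliptic threshold; samples with
    (vx/(lambda*sigma_x))^2 + (vy/(lambda*sigma_y))^2 > 1 lasting at least
    ``min_dur`` are events.  ``exclude_mask`` (True = usable) removes
    blink-padded samples from detection.
    """
    n = len(rec.time)
    if n < smooth_samples + 2:
        raise ValueError("recording shorter than the smoothing kernel")
    fs = rec.sampling_rate
    kernel = np.ones(smooth_samples) / smooth_samples
    vx = np.convolve(np.gradient(rec.gaze_x) * fs, kernel, mode="same")
    vy = np.convolve(np.gradient(rec.gaze_y) * fs, kernel, mode="same")
    usable = np.ones(n, dtype=bool) if exclude_mask is None else np.asarray(
        exclude_mask, dtype=bool
    )
    # median-estimator of the velocity noise scale (robust to the saccades
    # themselves)
    sigma = []
    for v in (vx, vy):
        vv = v[usable]
        med = np.median(vv)
        sd = np.sqrt(np.median((vv - med) ** 2))
        sigma.append(max(sd, 1e-12))
    rx, ry = lambda_thresh * sigma[0], lambda_thresh * sigma[1]
    crit = (vx / rx) ** 2 + (vy / ry) ** 2 > 1
    crit &= usable
    min_samples = max(1, int(round(min_dur * fs)))
    events = []
    speed = np.hypot(vx, vy)
    for start, stop in _runs(crit):
        if stop - start < min_samples:
            continue
        dx = rec.gaze_x[stop - 1] - rec.gaze_x[start]
        dy = rec.gaze_y[stop - 1] - rec.gaze_y[start]
        events.append(
            MicrosaccadeEvent(
                onset=start / fs,
                offset=stop / fs,
                amplitude=float(np.hypot(dx, dy)),
                peak_velocity=float(speed[start:stop].max()),
            )
        )
    return events


# ---------------------------------------------------------------------------
# epoching and rate timecourses


def epoch_eye(
    rec: EyeRecording,
    anchors,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    half_span: float = 6.0,
    blink_times=None,
    msacc_times=None,
) -> list[EyeEpoch]:
    """Crop half-open [-half_span, +half_span) epochs around each anchor.

    The pupil is baseline-subtracted by its mean over ``baseline_window``
    (relative to the anchor); blink and microsaccade event times (absolute
    seconds) are re-expressed relative to the anchor.  Anchors closer than
    ``half_span`` to either recording edge are dropped (count logged).
    """
    fs = rec.sampling_rate
    n_half = int(round(half_span * fs))
    rel_times = (np.arange(2 * n_half) - n_half) / fs
    blink_times = np.asarray(blink_times if blink_times is not None else [], float)
    msacc_times = np.asarray(msacc_times if msacc_times is not None else [], float)
    epochs = []
    dropped = 0
    for anchor in np.atleast_1d(np.asarray(anchors, dtype=float)):
        center = int(round(anchor * fs))
        lo, hi = center - n_half, center + n_half
        if lo < 0 or hi > len(rec.time):
            dropped += 1
            continue
        pupil = rec.pupil[lo:hi].astype(float)
        bmask = (rel_times >= baseline_window[0]) & (rel_times < baseline_window[1])
        corrected = pupil - pupil[bmask].mean()
        in_ep = lambda t: (t >= anchor - half_span) & (t < anchor + half_span)
        epochs.append(
            EyeEpoch(
                anchor=float(anchor),
                times=rel_times,
                pupil_corrected=corrected,
                blink_times=blink_times[in_ep(blink_times)] - anchor,
                msacc_times=msacc_times[in_ep(msacc_times)] - anchor,
                valid_fraction=float(rec.valid[lo:hi].mean()),
            )
        )
    if dropped:
        log.info("epoch_eye: dropped %d anchors too close to recording edges", dropped)
    return epochs


def event_rate_timecourse(
    epochs: list[EyeEpoch], which: str, bin_width: float = 0.5
) -> RateTimecourse:
    """Event rate (events/s) per time bin pooled over epochs, with
    across-epoch SEM."""
    if not epochs:
        raise ValueError("need at least one epoch")
    if which not in ("blink", "msacc"):
        raise ValueError("which must be 'blink' or 'msacc'")
    t0, t1 = epochs[0].times[0], epochs[0].times[-1]
    edges = np.arange(t0, t1 + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    counts = np.zeros((len(epochs), len(centers)))
    for i, ep in enumerate(epochs):
        ev = ep.blink_times if which == "blink" else ep.msacc_times
        counts[i], _ = np.histogram(ev, bins=edges)
    rates = counts / bin_width
    return RateTimecourse(
        bin_centers=centers,
        rate=rates.mean(axis=0),
        n_trials=len(epochs),
        sem=rates.std(axis=0, ddof=1) / np.sqrt(len(epochs))
        if len(epochs) > 1
        else np.zeros(len(centers)),
    )


def compare_eye_timecourses(
    epochs_a: list[EyeEpoch],
    epochs_b: list[EyeEpoch],
    signal: str = "pupil",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    bin_width: float = 0.5,
) -> clusterstat.ClusterTestResult:
    """Temporal cluster-based permutation test between two epoch groups.

    ``signal`` is one of pupil | blink | msacc.  Trial-level (or
    participant-level, if each entry is already an average) timecourses for
    group A minus the group-B mean are tested against zero with temporal
    adjacency only.  With unequal group sizes the difference is formed by
    pairing each A entry with the B mean; for a paired design pass equal-
    length groups in matching order.
    """
    if not epochs_a or not epochs_b:
        raise ValueError("both groups must be non-empty")

    def _matrix(epochs):
        if signal == "pupil":
            return np.stack([ep.pupil_corrected for ep in epochs]), epochs[0].times
        tc = [
            event_rate_timecourse([ep], which=signal, bin_width=bin_width)
            for ep in epochs
        ]
        return np.stack([r.rate for r in tc]), tc[0].bin_centers

    a, times = _matrix(epochs_a)
    b, _ = _matrix(epochs_b)
    if a.shape[0] == b.shape[0]:
        diff = a - b
    else:
        diff = a - b.mean(axis=0, keepdims=True)
    cube = clusterstat.DataCube(values=diff[:, None, :], times=times)
    config = clusterstat.ClusterTestConfig(alpha=alpha, n_perm=n_perm, seed=seed)
    return clusterstat.permutation_test(cube, config, mode="temporal_only")
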