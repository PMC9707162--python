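"""Synthetic eye-tracking sessions with perception-locked dynamics.

Consciously perceived stimuli evoke (1) a transient pupil dilation modeled
as a gamma-shaped impulse response, (2) a multiplicative blink-rate increase
in a post-stimulus window, and (3) a multiplicative microsaccade-rate
suppression shortly after the stimulus.  Blinks and microsaccades are
inhomogeneous Poisson point processes (sampled by thinning); blinks are
rendered as invalid, zeroed pupil runs and microsaccades as small ballistic
gaze steps.  Pupil noise has a white component plus a slow drift component
(moving-average of white noise), mimicking the dominant low-frequency
variability of real pupillometry that makes single-trial classification
nontrivial.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .._rng import substream
from ..eyeproc import (
    EyeEpoch,
    EyeRecording,
    detect_blinks,
    detect_microsaccades,
    epoch_eye,
    interpolate_artifacts,
)
from ..paradigm import StimulusEvent

__all__ = [
    "EyeDynamicsParams",
    "pupil_impulse_response",
    "generate_eye_session",
    "generate_isi_segments",
]


@dataclass(frozen=True)
class EyeDynamicsParams:
    """Generative parameters for perception-locked eye dynamics.

    Rates are events/s; pupil values are arbitrary units (a.u.) on an
    EyeLink-like scale with baseline ~1000 a.u.
    """

    pupil_baseline: float = 1000.0
    pupil_dilation_amp: float = 40.0  # a.u., peak of the impulse response
    pupil_peak_latency: float = 1.2  # s
    pupil_gamma_shape: float = 2.0
    blink_rate_base: float = 0.3
    blink_rate_gain_perceived: float = 2.0
    blink_gain_window: tuple[float, float] = (0.5, 2.0)
    blink_duration: tuple[float, float] = (0.1, 0.3)
    msacc_rate_base: float = 1.0
    msacc_suppression_factor: float = 0.3
    msacc_suppression_window: tuple[float, float] = (0.0, 1.0)
    msacc_amplitude: tuple[float, float] = (0.1, 0.5)  # deg
    msacc_duration: float = 0.02  # s
    noise_sd: float = 10.0  # white pupil noise, a.u.
    drift_sd: float = 30.0  # slow pupil drift, a.u.
    drift_window: float = 2.0  # s, moving-average length of the drift
    gaze_noise_sd: float = 0.005  # deg
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if min(self.blink_rate_base, self.msacc_rate_base) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.msacc_suppression_factor <= 1:
            raise ValueError("msacc_suppression_factor must lie in [0, 1]")


def pupil_impulse_response(
    t: np.ndarray, peak_latency: float, shape: float = 2.0
) -> np.ndarray:
    """Gamma-shaped kernel normalized to unit peak at ``peak_latency``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    k = shape
    # gamma density with mode at peak_latency, rescaled to peak value 1
    tp = t[pos] / peak_latency
    out[pos] = tp ** (k - 1) * np.exp((k - 1) * (1 - tp))
    return out


def _modulated_rate_events(
    rng: np.random.Generator,
    duration: float,
    base_rate: float,
    windows: np.ndarray,  # (n, 2) absolute intervals where the factor applies
    factor: float,
) -> np.ndarray:
    """Inhomogeneous Poisson event times by thinning."""
    peak = base_rate * max(1.0, factor)
    if peak <= 0 or duration <= 0:
        return np.array([])
    n = rng.poisson(peak * duration)
    t = np.sort(rng.uniform(0, duration, size=n))
    in_win = np.zeros(len(t), dtype=bool)
    for lo, hi in windows:
        in_win |= (t >= lo) & (t < hi)
    rate = np.where(in_win, base_rate * factor, base_rate)
    keep = rng.random(len(t)) < rate / peak
    return t[keep]


def generate_eye_session(
    schedule: Sequence[StimulusEvent],
    labels: Sequence[bool],
    params: EyeDynamicsParams | None = None,
    seed: int = 0,
    tail: float = 8.0,
) -> EyeRecording:
    """Simulate a continuous eye recording for a stimulus schedule.

    ``labels`` holds one perceived flag per schedule event.  The recording
    spans from 0 s to ``tail`` seconds past the last event.  Ground-truth
    event times are stored in ``recording.info`` under ``blink_times`` and
    ``msacc_times``.
    """
    if params is None:
        params = EyeDynamicsParams()
    onsets = np.asarray([e.onset for e in schedule], dtype=float)
    if len(onsets) and np.any(np.diff(onsets) <= 0):
        raise ValueError("schedule times must be strictly increasing")
    if len(onsets) != len(labels):
        raise ValueError("one label per schedule event required")
    if len(onsets) > 1 and np.any(np.diff(onsets) < 6.0):
        warnings.warn(
            "event windows overlap within epoch spacing; events honored independently"
        )
    fs = params.sampling_rate
    duration = (onsets[-1] + tail) if len(onsets) else tail
    n = int(round(duration * fs))
    time = np.arange(n) / fs

    rng_noise = substream(seed, "eye", "noise")
    pupil = params.pupil_baseline + params.noise_sd * rng_noise.standard_normal(n)
    if params.drift_sd > 0:
        L = max(1, int(round(params.drift_window * fs)))
        white = rng_noise.standard_normal(n + L - 1)
        drift = fftconvolve(white, np.ones(L) / L, mode="valid")[:n]
        pupil += params.drift_sd * np.sqrt(L) * drift

    perceived_onsets = onsets[np.asarray(labels, dtype=bool)]
    for onset in perceived_onsets:
        lo = int(round(onset * fs))
        hi = min(n, lo + int(round(6.0 * fs)))
        tt = time[lo:hi] - onset
        pupil[lo:hi] += params.pupil_dilation_amp * pupil_impulse_response(
            tt, params.pupil_peak_latency, params.pupil_gamma_shape
        )

    # blink events: rate multiplied in a post-event window after perceived events
    w0, w1 = params.blink_gain_window
    blink_windows = np.column_stack(
        [perceived_onsets + w0, perceived_onsets + w1]
    ) if len(perceived_onsets) else np.empty((0, 2))
    rng_blink = substream(seed, "eye", "blinks")
    blink_times = _modulated_rate_events(
        rng_blink, duration, params.blink_rate_base, blink_windows,
        params.blink_rate_gain_perceived,
    )
    valid = np.ones(n, dtype=bool)
    for bt in blink_times:
        dur = rng_blink.uniform(*params.blink_duration)
        lo, hi = int(round(bt * fs)), min(n, int(round((bt + dur) * fs)))
        pupil[lo:hi] = 0.0
        valid[lo:hi] = False

    # microsaccades: rate multiplied (suppressed) inside the post-event window
    s0, s1 = params.msacc_suppression_window
    supp_windows = np.column_stack(
        [perceived_onsets + s0, perceived_onsets + s1]
    ) if len(perceived_onsets) else np.empty((0, 2))
    rng_ms = substream(seed, "eye", "msaccs")
    msacc_times = _modulated_rate_events(
        rng_ms, duration, params.msacc_rate_base, supp_windows,
        params.msacc_suppression_factor,
    )
    gaze_x = params.gaze_noise_sd * rng_noise.standard_normal(n)
    gaze_y = params.gaze_noise_sd * rng_noise.standard_normal(n)
    pos = np.zeros(2)
    step_samples = max(2, int(round(params.msacc_duration * fs)))
    ramp = (1 - np.cos(np.linspace(0, np.pi, step_samples))) / 2  # smooth ballistic
    offset_x = np.zeros(n)
    offset_y = np.zeros(n)
    for mt in msacc_times:
        amp = rng_ms.uniform(*params.msacc_amplitude)
        # fixational: drift back toward the fixation cross when eccentric
        if np.hypot(*pos) > 0.5:
            angle = np.arctan2(-pos[1], -pos[0]) + rng_ms.normal(0, 0.3)
        else:
            angle = rng_ms.uniform(0, 2 * np.pi)
        step = amp * np.array([np.cos(angle), np.sin(angle)])
        lo = int(round(mt * fs))
        hi = min(n, lo + step_samples)
        if lo >= n:
            continue
        seg = ramp[: hi - lo]
        offset_x[lo:hi] = pos[0] + seg * step[0]
        offset_y[lo:hi] = pos[1] + seg * step[1]
        pos = pos + step
        offset_x[hi:] = pos[0]
        offset_y[hi:] = pos[1]
    gaze_x += offset_x
    gaze_y += offset_y

    return EyeRecording(
        time=time,
        pupil=pupil,
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        valid=valid,
        sampling_rate=fs,
        info={
            "blink_times": blink_times,
            "msacc_times": msacc_times,
            "params": params,
            "perceived_onsets": perceived_onsets,
        },
    )


def generate_isi_segments(
    schedule: Sequence[StimulusEvent],
    recording: EyeRecording,
    arousal_events: Sequence[float] | None = None,
    params: EyeDynamicsParams | None = None,
    epoch_half: float = 6.0,
    seed: int = 0,
) -> list[tuple[float, EyeEpoch]]:
    """Anchor one 12-s epoch at the midpoint of each qualifying ISI.

    An interstimulus interval runs from one presentation onset to the next;
    it qualifies when it can contain a full epoch
    (length >= 2 * epoch_half) that also fits inside the recording.  The
    anchor ("center time") is the arithmetic midpoint of the interval.

    ``arousal_events`` optionally lists absolute times at which a spontaneous
    arousal transient -- the perceived-stimulus pupil template plus extra
    blinks at the perceived blink rate -- is injected before epoching,
    emulating stimulus-free fluctuations in conscious awareness.

    Epochs are produced through the standard processing chain (blink
    detection, artifact interpolation, microsaccade detection).
    """
    if params is None:
        params = recording.info.get("params", EyeDynamicsParams())
    rec = recording.copy()
    fs = rec.sampling_rate
    n = len(rec.time)
    if arousal_events:
        rng = substream(seed, "isi", "arousal")
        for at in arousal_events:
            lo = int(round(at * fs))
            hi = min(n, lo + int(round(6.0 * fs)))
            tt = rec.time[lo:hi] - at
            rec.pupil[lo:hi] += params.pupil_dilation_amp * pupil_impulse_response(
                tt, params.pupil_peak_latency, params.pupil_gamma_shape
            )
            extra_rate = params.blink_rate_base * (
                params.blink_rate_gain_perceived - 1
            )
            w0, w1 = params.blink_gain_window
            n_extra = rng.poisson(extra_rate * (w1 - w0))
            for bt in rng.uniform(at + w0, at + w1, size=n_extra):
                dur = rng.uniform(*params.blink_duration)
                blo, bhi = int(round(bt * fs)), min(n, int(round((bt + dur) * fs)))
                rec.pupil[blo:bhi] = 0.0
                rec.valid[blo:bhi] = False

    onsets = np.asarray([e.onset for e in schedule], dtype=float)
    centers = []
    for i in range(len(onsets) - 1):
        start = onsets[i]
        stop = onsets[i + 1]
        if stop - start < 2 * epoch_half:
            continue
        center = (start + stop) / 2
        if center - epoch_half < 0 or center + epoch_half > rec.duration:
            continue
        centers.append(center)
    if not centers:
        return []

    blinks, _ = detect_blinks(rec)
    interp = interpolate_artifacts(rec, blinks)
    msaccs = detect_microsaccades(
        interp, exclude_mask=interp.info["artifact_valid"]
    )
    epochs = epoch_eye(
        interp,
        centers,
        half_span=epoch_half,
        blink_times=[b[0] for b in blinks],
        msacc_times=[m.onset for m in msaccs],
    )
    return list(zip(centers, epochs))
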