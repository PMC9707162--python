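"""Synthetic EEG epochs with perception- and report-dependent components.

Scalp components are Gaussian-envelope deflections with per-channel weights:
N100 (present for every stimulus), VAN (perceived stimuli, report or not),
N2 and P3 (perceived stimuli under overt report only).  A biphasic thalamic
awareness potential (TAP) template -- the difference of two gamma kernels
with onset ~250 ms and first peak ~430 ms -- is available for depth-channel
simulations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .._rng import substream
from ..erp import EEGEpochSet

__all__ = [
    "ErpComponent",
    "ErpTemplateSet",
    "default_erp_templates",
    "tap_template",
    "generate_eeg_epochs",
]

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "O1", "O2", "P3", "P4")


@dataclass(frozen=True)
class ErpComponent:
    name: str
    polarity: int  # +1 / -1
    peak_latency: float  # s
    width: float  # s, Gaussian sigma
    channel_weights: tuple[float, ...]
    amplitude: float  # uV at the peak of the strongest channel
    report_dependent: bool = False
    perception_dependent: bool = True

    def waveform(self, times: np.ndarray) -> np.ndarray:
        env = np.exp(-0.5 * ((times - self.peak_latency) / self.width) ** 2)
        return self.polarity * self.amplitude * env


@dataclass(frozen=True)
class ErpTemplateSet:
    components: tuple[ErpComponent, ...]
    noise_sd: float = 5.0  # uV
    sampling_rate: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    tmin: float = -0.5
    tmax: float = 1.5

    def __post_init__(self) -> None:
        for c in self.components:
            if len(c.channel_weights) == 0:
                raise ValueError(f"component {c.name} has empty channel_weights")
            if len(c.channel_weights) != len(self.channels):
                raise ValueError(
                    f"component {c.name}: channel_weights must match channels"
                )

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sampling_rate))
        return self.tmin + np.arange(n) / self.sampling_rate


def tap_template(
    times: np.ndarray,
    onset: float = 0.25,
    first_peak: float = 0.43,
    amplitude: float = 8.0,
    rebound: float = 0.8,
) -> np.ndarray:
    """Biphasic thalamic potential: difference of two gamma kernels, zero
    before ``onset``, positive first peak at ``first_peak``, later negative
    phase."""
    t = np.asarray(times, dtype=float)

    def gamma_kernel(tt, mode, k=2.0):
        out = np.zeros_like(tt)
        pos = tt > 0
        x = tt[pos] / mode
        out[pos] = x ** (k - 1) * np.exp((k - 1) * (1 - x))
        return out

    mode1 = first_peak - onset
    # second (negative) phase begins at the first peak, so the positive
    # extremum stays exactly at first_peak
    wave = gamma_kernel(t - onset, mode1) - rebound * gamma_kernel(
        t - first_peak, 2.0 * mode1
    )
    return amplitude * wave


def default_erp_templates(noise_sd: float = 5.0) -> ErpTemplateSet:
    """Scalp montage template set with posterior-weighted visual components."""
    posterior = (0.1, 0.4, 0.8, 1.0, 0.9, 0.9, 0.7, 0.7)
    centroparietal = (0.4, 0.8, 1.0, 0.5, 0.4, 0.4, 0.8, 0.8)
    comps = (
        ErpComponent("N100", -1, 0.100, 0.015, posterior, 4.0,
                     report_dependent=False, perception_dependent=False),
        ErpComponent("VAN", -1, 0.200, 0.020, posterior, 5.0,
                     report_dependent=False, perception_dependent=True),
        ErpComponent("N2", -1, 0.300, 0.020, centroparietal, 4.0,
                     report_dependent=True, perception_dependent=True),
        ErpComponent("P3", +1, 0.500, 0.080, centroparietal, 6.0,
                     report_dependent=True, perception_dependent=True),
    )
    return ErpTemplateSet(components=comps, noise_sd=noise_sd)


def noiseless_epoch(
    templates: ErpTemplateSet, perceived: bool, condition: str
) -> np.ndarray:
    """Deterministic channels x time epoch for one trial type."""
    times = templates.times
    out = np.zeros((len(templates.channels), len(times)))
    for comp in templates.components:
        if comp.perception_dependent and not perceived:
            continue
        if comp.report_dependent and condition != "report":
            continue
        wave = comp.waveform(times)
        out += np.outer(np.asarray(comp.channel_weights), wave)
    return out


def generate_eeg_epochs(
    n_participants: int,
    n_trials_per_cell: int,
    templates: ErpTemplateSet | None = None,
    condition: str = "no_report",
    seed: int = 0,
    participant_scale_sd: float = 0.15,
) -> list[EEGEpochSet]:
    """One EEGEpochSet per participant with perceived and not-perceived cells.

    Perceived epochs contain the perception-dependent components;
    report-dependent components appear only when ``condition == 'report'``.
    Additive white Gaussian channel noise; each participant carries a mild
    multiplicative amplitude factor (component amplitudes scale linearly).
    """
    if templates is None:
        templates = default_erp_templates()
    if n_trials_per_cell < 1:
        raise ValueError("n_trials_per_cell must be >= 1")
    if condition not in ("report", "no_report"):
        raise ValueError("condition must be 'report' or 'no_report'")
    times = templates.times
    n_ch = len(templates.channels)
    base = {
        True: noiseless_epoch(templates, True, condition),
        False: noiseless_epoch(templates, False, condition),
    }
    out = []
    for p in range(n_participants):
        rng = substream(seed, "eeg", condition, p)
        scale = max(0.2, 1.0 + participant_scale_sd * rng.standard_normal())
        epochs = np.empty((n_ch, len(times), 2 * n_trials_per_cell))
        labels = np.zeros(2 * n_trials_per_cell, dtype=bool)
        for k in range(2 * n_trials_per_cell):
            perceived = k < n_trials_per_cell
            labels[k] = perceived
            epochs[:, :, k] = scale * base[perceived] + (
                templates.noise_sd * rng.standard_normal((n_ch, len(times)))
            )
        out.append(
            EEGEpochSet(
                epochs=epochs,
                channels=list(templates.channels),
                times=times,
                perceived=labels,
                condition=condition,
            )
        )
    return out
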