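"""Synthetic BOLD sessions on a small labeled voxel grid.

Three disjoint network masks carry the canonical perceived-minus-not
timecourses: DAS (detection/arousal/salience) positive with an early peak
in the 3-4 s bin, TPN (task-positive) positive peaking ~6 s, DMN (default
mode) negative with a trough in the 6-8 s bin.  Remaining voxels are null
(noise only), so their group t statistics follow t(N-1) exactly.  The grid
is integer-labeled with no real anatomy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from ..fmri import BoldEpochSet

__all__ = [
    "BoldTemplateSet",
    "default_bold_templates",
    "generate_fmri_session",
    "testing_run_volume_count",
    "generate_fmri_run",
    "RUN_DURATIONS_S",
]

# testing/calibration run lengths by paradigm (seconds); one volume per TR
RUN_DURATIONS_S = {
    ("report", "testing"): 720.0,
    ("report_noreport", "testing"): 700.0,
    ("report", "calibration"): 270.0,
    ("report_noreport", "calibration"): 600.0,
}


def _gamma_bump(t: np.ndarray, mode: float, k: float = 3.0) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / mode
    out[pos] = x ** (k - 1) * np.exp((k - 1) * (1 - x))
    return out


@dataclass(frozen=True)
class BoldTemplateSet:
    grid_dims: tuple[int, int, int] = (20, 20, 12)
    voxel_size: float = 2.0  # mm
    tr: float = 1.0  # s
    epoch_window: tuple[float, float] = (-20.0, 20.0)
    das_peak: float = 3.5  # s
    tpn_peak: float = 6.0  # s
    dmn_trough: float = 7.0  # s
    das_amp: float = 0.8  # percent-change peak
    tpn_amp: float = 0.6
    dmn_amp: float = -0.6
    noise_sd: float = 0.4  # percent-change units, at the epoch-average level

    @property
    def times(self) -> np.ndarray:
        lo, hi = self.epoch_window
        return np.arange(lo, hi + self.tr / 2, self.tr)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def network_masks(self) -> dict[str, np.ndarray]:
        """Disjoint integer-grid masks (flattened boolean) for each network."""
        gx, gy, gz = self.grid_dims
        vol = np.zeros(self.grid_dims, dtype="U3")
        blocks = {
            "DAS": (slice(2, 7), slice(3, 9), slice(3, 8)),
            "TPN": (slice(8, 13), slice(3, 9), slice(3, 8)),
            "DMN": (slice(14, 19), slice(3, 9), slice(3, 8)),
        }
        out = {}
        for name, sl in blocks.items():
            m = np.zeros(self.grid_dims, dtype=bool)
            m[sl] = True
            if m.shape != tuple(self.grid_dims) or (
                sl[0].stop > gx or sl[1].stop > gy or sl[2].stop > gz
            ):
                raise ValueError(f"network mask {name} outside grid")
            out[name] = m.ravel()
        return out

    def network_timecourses(self) -> dict[str, np.ndarray]:
        t = self.times
        return {
            "DAS": self.das_amp * _gamma_bump(t, self.das_peak),
            "TPN": self.tpn_amp * _gamma_bump(t, self.tpn_peak),
            "DMN": self.dmn_amp * _gamma_bump(t, self.dmn_trough),
        }


def default_bold_templates(**overrides) -> BoldTemplateSet:
    return BoldTemplateSet(**overrides)


@dataclass
class BoldSession:
    perceived: BoldEpochSet
    not_perceived: BoldEpochSet
    templates: BoldTemplateSet

    @property
    def difference(self) -> np.ndarray:
        return self.perceived.percent_change - self.not_perceived.percent_change


def generate_fmri_session(
    n_participants: int,
    n_events_per_condition: int,
    templates: BoldTemplateSet | None = None,
    condition: str = "no_report",
    seed: int = 0,
    participant_scale_sd: float = 0.2,
) -> BoldSession:
    """Participant-level percent-change epoch sets for both conditions.

    Perceived epochs add each network's template inside its mask; the
    per-participant epoch average carries Gaussian noise with SD
    ``noise_sd / sqrt(n_events_per_condition)`` (trial averaging) plus a
    mild multiplicative amplitude factor per participant.
    """
    if templates is None:
        templates = BoldTemplateSet()
    masks = templates.network_masks()
    tcs = templates.network_timecourses()
    times = templates.times
    n_vox = templates.n_voxels
    n_time = len(times)
    signal = np.zeros((n_vox, n_time))
    for name, mask in masks.items():
        signal[mask] += tcs[name]

    eff_sd = templates.noise_sd / np.sqrt(max(1, n_events_per_condition))
    data = {}
    rng = substream(seed, "fmri", condition)
    scales = np.maximum(0.2, 1.0 + participant_scale_sd * rng.standard_normal(n_participants))
    for label, with_signal in (("perceived", True), ("not_perceived", False)):
        arr = eff_sd * rng.standard_normal((n_participants, n_vox, n_time))
        if with_signal:
            arr += scales[:, None, None] * signal[None]
        data[label] = BoldEpochSet(
            percent_change=arr,
            grid_dims=templates.grid_dims,
            times=times,
            condition=f"{condition}:{label}",
        )
    return BoldSession(data["perceived"], data["not_perceived"], templates)


def testing_run_volume_count(
    paradigm: str = "report", phase: str = "testing", tr: float = 1.0
) -> int:
    """Number of volumes in one scan run: run seconds / TR (TR = 1 s)."""
    return int(round(RUN_DURATIONS_S[(paradigm, phase)] / tr))


def generate_fmri_run(
    paradigm: str = "report",
    phase: str = "testing",
    templates: BoldTemplateSet | None = None,
    seed: int = 0,
    baseline: float = 1000.0,
    noise_sd: float = 5.0,
    event_onsets=None,
) -> np.ndarray:
    """A continuous 4-D scan (x, y, z, volumes) for one run.

    The volume count equals the run duration at the stated TR.  Optional
    ``event_onsets`` (seconds, perceived events) add the network templates
    as fractional signal change on the baseline.
    """
    if templates is None:
        templates = BoldTemplateSet()
    n_vol = testing_run_volume_count(paradigm, phase, templates.tr)
    rng = substream(seed, "fmri_run", paradigm, phase)
    n_vox = templates.n_voxels
    data = baseline + noise_sd * rng.standard_normal((n_vox, n_vol))
    if event_onsets is not None:
        masks = templates.network_masks()
        tcs = templates.network_timecourses()
        times = templates.times
        post = times >= 0
        for onset in np.atleast_1d(event_onsets):
            v0 = int(round(onset / templates.tr))
            seg = slice(v0, min(n_vol, v0 + int(post.sum())))
            n_seg = seg.stop - seg.start
            for name, mask in masks.items():
                data[mask, seg] += baseline * tcs[name][post][:n_seg] / 100.0
    return data.reshape(*templates.grid_dims, n_vol)
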