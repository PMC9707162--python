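"""Threshold visual perception paradigm: schedules, psychometric fit, scoring.

The paradigm has two phases.  A *calibration* phase presents a brief (50 ms)
face at one of 25 opacity levels spanning 0.01-0.25 in each of 8 screen
locations (two location sets: four quadrant, four central positions), twice
per location, for 400 stimuli total; detection responses are fitted with a
sigmoidal (logistic) psychometric function per location set to estimate the
perceptual-threshold opacity (the 50% detection point).  A *testing* phase
runs trials of six jittered phases where each of two stimuli per trial is
blank (12.5%), at the estimated threshold (75%), or fully opaque (12.5%);
one location set is task-relevant (report) and the other task-irrelevant
(no-report).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, xlogy

from ._rng import substream

__all__ = [
    "ParadigmConfig",
    "StimulusEvent",
    "TrialRecord",
    "PsychometricFit",
    "build_calibration_schedule",
    "fit_psychometric",
    "build_testing_schedule",
    "events_of",
    "score_behavior",
]

LOCATION_SETS = ("quadrant", "central")
OPACITY_CONDITIONS = ("blank", "threshold", "opaque", "calibration")


@dataclass(frozen=True)
class ParadigmConfig:
    n_opacity_levels: int = 25
    opacity_range: tuple[float, float] = (0.01, 0.25)
    n_locations_per_set: int = 4
    n_sets: int = 2
    calib_reps_per_location: int = 2
    trials_per_run: int = 24
    opacity_condition_probs: tuple[float, float, float] = (0.125, 0.75, 0.125)
    stimulus_duration: float = 0.05
    phase_jitter: tuple[float, float] = (6.0, 10.0)
    calib_isi_jitter: tuple[float, float] = (1.0, 1.5)
    response_duration: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if abs(sum(self.opacity_condition_probs) - 1.0) > 1e-9:
            raise ValueError("opacity condition probabilities must sum to 1")
        if self.n_opacity_levels < 2:
            raise ValueError("need at least 2 opacity levels")

    @property
    def opacity_grid(self) -> np.ndarray:
        lo, hi = self.opacity_range
        return np.linspace(lo, hi, self.n_opacity_levels)


@dataclass
class StimulusEvent:
    onset: float
    location_set: str  # quadrant | central
    location: int  # 1..4
    opacity_condition: str  # blank | threshold | opaque | calibration
    opacity: float
    relevance: str | None = None  # report | no_report (testing phase only)
    response_seen: bool | None = None
    response_location: int | None = None

    def __post_init__(self) -> None:
        if self.location_set not in LOCATION_SETS:
            raise ValueError(f"unknown location set {self.location_set!r}")
        if self.opacity_condition not in OPACITY_CONDITIONS:
            raise ValueError(f"unknown condition {self.opacity_condition!r}")
        if self.opacity_condition == "blank" and self.opacity != 0:
            raise ValueError("blank stimuli must have opacity 0")
        if self.opacity_condition == "opaque" and self.opacity != 1:
            raise ValueError("opaque stimuli must have opacity 1")
        if not 0 <= self.opacity <= 1:
            raise ValueError("opacity must lie in [0, 1]")
        if self.relevance == "no_report" and (
            self.response_seen is not None or self.response_location is not None
        ):
            raise ValueError("no-report stimuli carry no overt responses")


@dataclass
class TrialRecord:
    run_index: int
    trial_index: int
    phase_onsets: dict
    stimuli: list  # two StimulusEvent entries (first, second)


def build_calibration_schedule(
    config: ParadigmConfig, seed: int
) -> list[StimulusEvent]:
    """Every (opacity level, location) pair, ``calib_reps_per_location``
    times, in randomized order with 1-1.5 s jittered inter-onset gaps."""
    rng = substream(seed, "calibration_schedule")
    cells = [
        (float(op), ls, loc)
        for op in config.opacity_grid
        for ls in LOCATION_SETS[: config.n_sets]
        for loc in range(1, config.n_locations_per_set + 1)
        for _ in range(config.calib_reps_per_location)
    ]
    order = rng.permutation(len(cells))
    lo, hi = config.calib_isi_jitter
    gaps = rng.uniform(lo, hi, size=len(cells))
    onset = 2.0
    events = []
    for k, gap in zip(order, gaps):
        op, ls, loc = cells[k]
        events.append(
            StimulusEvent(
                onset=onset,
                location_set=ls,
                location=loc,
                opacity_condition="calibration",
                opacity=op,
            )
        )
        onset += gap
    return events


# ---------------------------------------------------------------------------
# psychometric fit


@dataclass
class PsychometricFit:
    threshold_opacity: float
    slope: float
    lapse_rate: float
    guess_rate: float
    fit_loss: float
    converged: bool

    def p_seen(self, opacity) -> np.ndarray:
        op = np.asarray(opacity, dtype=float)
        core = expit(self.slope * (op - self.threshold_opacity))
        return self.guess_rate + (1 - self.guess_rate - self.lapse_rate) * core


def _nll(params, x, seen, include_lapse):
    if include_lapse:
        theta, slope, lapse, guess = params
    else:
        theta, slope = params
        lapse = guess = 0.0
    p = guess + (1 - guess - lapse) * expit(slope * (x - theta))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -float(np.sum(xlogy(seen, p) + xlogy(1 - seen, 1 - p)))


def fit_psychometric(
    responses: Sequence[tuple[float, bool]],
    config: ParadigmConfig | None = None,
    include_lapse: bool = True,
) -> PsychometricFit:
    """Maximum-likelihood logistic psychometric fit.

    ``responses`` is a sequence of (opacity, seen) pairs from one location
    set.  The threshold is the opacity at which the lapse/guess-corrected
    curve crosses 0.5 (the logistic midpoint).  Degenerate all-seen or
    all-unseen data yield a non-converged fit with the threshold clamped to
    the nearer edge of the opacity range.  Bounded quasi-Newton (L-BFGS-B)
    with 5 restarts.
    """
    if config is None:
        config = ParadigmConfig()
    x = np.asarray([r[0] for r in responses], dtype=float)
    seen = np.asarray([bool(r[1]) for r in responses], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need responses at >= 2 distinct opacity levels")
    lo, hi = config.opacity_range
    if seen.all() or (~seen.astype(bool)).all():
        edge = lo if seen.all() else hi
        return PsychometricFit(edge, np.inf, 0.0, 0.0, 0.0, converged=False)

    span = x.max() - x.min()
    theta_bounds = (x.min() - span, x.max() + span)
    bounds = [theta_bounds, (1.0, 2000.0)]
    if include_lapse:
        bounds += [(0.0, 0.1), (0.0, 0.1)]
    starts = np.linspace(x.min(), x.max(), 5)
    best = None
    for i, theta0 in enumerate(starts):
        p0 = [theta0, [10, 40, 100, 40, 200][i]]
        if include_lapse:
            p0 += [0.01, 0.01]
        res = minimize(
            _nll, p0, args=(x, seen, include_lapse), method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, slope = best.x[0], best.x[1]
    lapse, guess = (best.x[2], best.x[3]) if include_lapse else (0.0, 0.0)
    converged = bool(best.success and lo <= theta <= hi)
    return PsychometricFit(
        threshold_opacity=float(theta),
        slope=float(slope),
        lapse_rate=float(lapse),
        guess_rate=float(guess),
        fit_loss=float(best.fun),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# testing phase


def build_testing_schedule(
    config: ParadigmConfig,
    thresholds: dict[str, PsychometricFit | float],
    relevant_set: str,
    n_runs: int,
    seed: int,
) -> list[TrialRecord]:
    """Testing-phase trials with six jittered phases and two stimuli each.

    The first stimulus is equally likely in either location set; the second
    falls in the complementary set.  Each stimulus is blank / threshold /
    opaque with the configured probabilities; threshold stimuli use the
    location set's estimated threshold opacity.  Stimuli in ``relevant_set``
    are report (task-relevant), the rest no-report.
    """
    if relevant_set not in LOCATION_SETS:
        raise ValueError(f"unknown location set {relevant_set!r}")
    thr = {
        ls: (v.threshold_opacity if isinstance(v, PsychometricFit) else float(v))
        for ls, v in thresholds.items()
    }
    for ls in LOCATION_SETS:
        if ls not in thr:
            raise ValueError(f"missing threshold for location set {ls!r}")
    rng = substream(seed, "testing_schedule")
    jlo, jhi = config.phase_jitter
    rlo, rhi = config.response_duration
    probs = np.asarray(config.opacity_condition_probs)
    trials: list[TrialRecord] = []
    t = 0.0
    for run in range(n_runs):
        for trial in range(config.trials_per_run):
            onsets = {}
            onsets["pre_stimulus"] = t
            t += rng.uniform(jlo, jhi)
            first_set = LOCATION_SETS[rng.integers(0, 2)]
            second_set = LOCATION_SETS[1 - LOCATION_SETS.index(first_set)]
            stimuli = []
            for phase, ls in (("first_stimulus", first_set), ("second_stimulus", second_set)):
                onsets[phase] = t
                cond = ("blank", "threshold", "opaque")[
                    rng.choice(3, p=probs)
                ]
                opacity = {"blank": 0.0, "threshold": thr[ls], "opaque": 1.0}[cond]
                stimuli.append(
                    StimulusEvent(
                        onset=t,
                        location_set=ls,
                        location=int(rng.integers(1, config.n_locations_per_set + 1)),
                        opacity_condition=cond,
                        opacity=opacity,
                        relevance="report" if ls == relevant_set else "no_report",
                    )
                )
                t += config.stimulus_duration
                jitter_name = "inter_stimulus" if phase == "first_stimulus" else "post_stimulus"
                onsets[jitter_name] = t
                t += rng.uniform(jlo, jhi)
            onsets["response"] = t
            t += rng.uniform(rlo, rhi)
            trials.append(
                TrialRecord(
                    run_index=run,
                    trial_index=trial,
                    phase_onsets=onsets,
                    stimuli=stimuli,
                )
            )
    return trials


def events_of(trials: Sequence[TrialRecord]) -> list[StimulusEvent]:
    """Flatten trial records to their stimulus events in onset order."""
    return [s for tr in trials for s in tr.stimuli]


def score_behavior(trials: Sequence[TrialRecord] | Sequence[StimulusEvent]) -> dict:
    """Behavioral summary over report (task-relevant) stimuli.

    Returns per-condition seen proportions, location accuracy for seen and
    not-seen responses, and the false-negative rate on fully opaque stimuli.
    Returns {} when no report stimuli carry responses.
    """
    if trials and isinstance(trials[0], TrialRecord):
        events = events_of(trials)  # type: ignore[arg-type]
    else:
        events = list(trials)  # type: ignore[assignment]
    report = [
        e for e in events if e.relevance == "report" and e.response_seen is not None
    ]
    if not report:
        return {}
    out: dict = {"n_report_responses": len(report), "seen_proportion": {}}
    for cond in ("blank", "threshold", "opaque"):
        sub = [e for e in report if e.opacity_condition == cond]
        if sub:
            out["seen_proportion"][cond] = float(
                np.mean([e.response_seen for e in sub])
            )
    for label, flag in (("seen", True), ("not_seen", False)):
        sub = [
            e
            for e in report
            if e.response_seen is flag
            and e.response_location is not None
            and e.opacity_condition != "blank"
        ]
        if sub:
            out[f"location_accuracy_{label}"] = float(
                np.mean([e.response_location == e.location for e in sub])
            )
    opaque = [e for e in report if e.opacity_condition == "opaque"]
    if opaque:
        out["false_negative_rate_opaque"] = float(
            np.mean([not e.response_seen for e in opaque])
        )
    return out
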