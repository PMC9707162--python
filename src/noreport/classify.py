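"""Covert perception classification from eye-movement features.

The pipeline mirrors the stages trial segmentation -> feature extraction ->
feature normalization -> feature selection -> information fusion ->
classification: windowed pupil, blink, and microsaccade features are
extracted per 12-s epoch, z-scaled on the training data, screened by
absolute two-sample t, fused by concatenation across modalities, and fed to
a regularized linear classifier whose signed decision score is thresholded
at 0 (score > 0 -> perceived).  The model is trained on report
(task-relevant) trials labeled by overt response and then applied unchanged
to no-report and interstimulus-interval (ISI) epochs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from ._rng import spawn_seed
from .eyeproc import EyeEpoch

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "extract_features",
    "feature_matrix",
    "TrainedPipeline",
    "train_pipeline",
    "classify",
    "classify_isi",
    "sort_isi_by_modality",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Windows (seconds relative to the anchor) for each feature family."""

    pupil_mean_windows: tuple = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))
    pupil_peak_window: tuple[float, float] = (0.0, 4.0)
    blink_count_windows: tuple = ((0.0, 1.0), (1.0, 2.0))
    msacc_count_windows: tuple = ((0.0, 0.5), (0.5, 1.0))
    count_baseline_window: tuple[float, float] = (-6.0, 0.0)
    top_k: int = 6


FEATURE_NAMES = (
    "pupil_mean_0_1",
    "pupil_mean_1_2",
    "pupil_mean_2_3",
    "pupil_peak",
    "pupil_peak_latency",
    "blink_count_0_1",
    "blink_count_1_2",
    "msacc_count_0_0.5",
    "msacc_count_0.5_1",
)

MODALITY_TAGS = (
    "pupil", "pupil", "pupil", "pupil", "pupil",
    "blink", "blink", "msacc", "msacc",
)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    modalities: tuple[str, ...] = MODALITY_TAGS
    flagged: bool = False  # True when the source epoch was unusable


def _window_mean(epoch: EyeEpoch, lo: float, hi: float) -> float:
    m = (epoch.times > lo) & (epoch.times <= hi)
    return float(epoch.pupil_corrected[m].mean())


def _count(times: np.ndarray, lo: float, hi: float) -> int:
    return int(np.count_nonzero((times > lo) & (times <= hi)))


def extract_features(
    epoch: EyeEpoch, config: FeatureConfig | None = None
) -> FeatureVector:
    """Deterministic feature mapping for one epoch.

    Pupil features use the baseline-corrected trace; blink and microsaccade
    counts subtract the epoch's own pre-anchor baseline rate scaled to the
    window width.  An all-invalid epoch yields a flagged vector (never a
    silent zero).
    """
    if config is None:
        config = FeatureConfig()
    if epoch.valid_fraction == 0:
        return FeatureVector(values=np.full(len(FEATURE_NAMES), np.nan), flagged=True)
    lo_t, hi_t = config.pupil_peak_window
    pk_mask = (epoch.times > lo_t) & (epoch.times <= hi_t)
    pk_trace = epoch.pupil_corrected[pk_mask]
    pk_i = int(np.argmax(pk_trace))
    b_lo, b_hi = config.count_baseline_window
    b_width = b_hi - b_lo
    vals = []
    for lo, hi in config.pupil_mean_windows:
        vals.append(_window_mean(epoch, lo, hi))
    vals.append(float(pk_trace[pk_i]))
    vals.append(float(epoch.times[pk_mask][pk_i]))
    for lo, hi in config.blink_count_windows:
        base = _count(epoch.blink_times, b_lo, b_hi) * (hi - lo) / b_width
        vals.append(_count(epoch.blink_times, lo, hi) - base)
    for lo, hi in config.msacc_count_windows:
        base = _count(epoch.msacc_times, b_lo, b_hi) * (hi - lo) / b_width
        vals.append(_count(epoch.msacc_times, lo, hi) - base)
    return FeatureVector(values=np.asarray(vals, dtype=float))


def feature_matrix(
    epochs: list[EyeEpoch], config: FeatureConfig | None = None
) -> np.ndarray:
    """Stack per-epoch feature vectors; flagged epochs become NaN rows."""
    return np.stack([extract_features(ep, config).values for ep in epochs])


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainedPipeline:
    mean: np.ndarray
    sd: np.ndarray
    selected: np.ndarray  # indices into the full feature vector
    coef: np.ndarray
    intercept: float
    threshold: float = 0.0
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.mean):
            raise ValueError("feature-length mismatch")
        z = (X - self.mean) / self.sd
        return z[:, self.selected] @ self.coef + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "selected": self.selected.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "threshold": self.threshold,
                "feature_names": list(self.feature_names),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedPipeline":
        d = json.loads(text)
        return cls(
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            selected=np.asarray(d["selected"], dtype=int),
            coef=np.asarray(d["coef"]),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            feature_names=tuple(d["feature_names"]),
        )


def _screen_features(z: np.ndarray, y: np.ndarray, top_k: int) -> np.ndarray:
    """Top-k columns by |two-sample t|, deterministic tie-break by index;
    at most one of any set of identical columns (first index wins)."""
    n_feat = z.shape[1]
    keep = np.ones(n_feat, dtype=bool)
    for j in range(n_feat):
        if not keep[j]:
            continue
        for l in range(j + 1, n_feat):
            if keep[l] and np.array_equal(z[:, j], z[:, l]):
                keep[l] = False
    tvals = np.zeros(n_feat)
    a, b = z[y.astype(bool)], z[~y.astype(bool)]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=0)
    # nan (no variance, no separation) ranks last; +/-inf (perfect
    # separation) ranks first
    tvals = np.where(np.isnan(t), 0.0, np.abs(t))
    tvals[~keep] = -np.inf
    order = np.argsort(-tvals, kind="stable")  # stable: ties to lower index
    return np.sort(order[: min(top_k, int(keep.sum()))])


def train_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    config: FeatureConfig | None = None,
    seed: int = 0,
    C: float = 1.0,
) -> TrainedPipeline:
    """Fit normalizer, selector, and linear classifier on report trials.

    ``y`` holds the overt perceived labels.  Rows with NaN (flagged epochs)
    are dropped from training.  The decision score is the logistic-regression
    decision function, so 0 is the class boundary.
    """
    if config is None:
        config = FeatureConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (X - mean) / sd
    selected = _screen_features(z, y, config.top_k)
    clf = LogisticRegression(
        C=C, solver="lbfgs", max_iter=1000, random_state=spawn_seed(seed, "clf")
    )
    clf.fit(z[:, selected], y)
    return TrainedPipeline(
        mean=mean,
        sd=sd,
        selected=selected,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
    )


@dataclass
class ClassifierOutput:
    score: float
    label: str  # perceived | not_perceived
    threshold: float = 0.0


def classify(pipeline: TrainedPipeline, X: np.ndarray) -> list[ClassifierOutput]:
    """Label epochs by the sign of the decision score vs the 0 threshold.

    A score exactly at the threshold is classed not_perceived (strict
    inequality).
    """
    scores = pipeline.scores(np.asarray(X, dtype=float))
    return [
        ClassifierOutput(
            score=float(s),
            label="perceived" if s > pipeline.threshold else "not_perceived",
            threshold=pipeline.threshold,
        )
        for s in scores
    ]


def classify_isi(
    pipeline: TrainedPipeline, isi_epochs: list[EyeEpoch],
    config: FeatureConfig | None = None,
) -> list[ClassifierOutput]:
    """Apply the trained pipeline unchanged to ISI-anchored epochs."""
    return classify(pipeline, feature_matrix(isi_epochs, config))


# summary feature per modality used for single-modality ISI sorting
_SORT_SUMMARY = {
    "pupil": lambda ep: _window_mean(ep, 0.0, 2.0),
    "blink": lambda ep: _count(ep.blink_times, 0.0, 2.0),
    "msacc": lambda ep: _count(ep.msacc_times, 0.0, 1.0),
}


def sort_isi_by_modality(
    isi_epochs: list[EyeEpoch], modality: str
) -> tuple[list[int], list[int]]:
    """Median split of ISI epochs on a single modality's summary feature.

    Returns (high indices, low indices).  Values equal to the median go to
    the low set, so with odd n the low set gets the extra element.
    """
    if modality not in _SORT_SUMMARY:
        raise ValueError(f"unknown modality {modality!r}")
    if len(isi_epochs) < 2:
        raise ValueError("need at least 2 epochs to sort")
    vals = np.asarray([_SORT_SUMMARY[modality](ep) for ep in isi_epochs], float)
    if np.all(vals == vals[0]):
        raise ValueError("unsortable: constant summary feature")
    med = float(np.median(vals))
    high = [i for i, v in enumerate(vals) if v > med]
    low = [i for i, v in enumerate(vals) if v <= med]
    return high, low
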