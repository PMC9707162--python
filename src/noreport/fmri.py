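"""Percent-change BOLD analyses and data-driven network mapping.

Event-related BOLD epochs are expressed as percent change from a short
pre-event baseline.  Perceived-minus-not-perceived participant maps feed a
spatiotemporal cluster-based permutation test (6-connected voxels, +/-1 TR);
conjunction and exclusive-disjunction maps compare the significant
voxel-time sets of two contrasts; eye-movement-related signal is removed
from the no-report contrast by a three-way conjunction against pupil-,
blink-, and microsaccade-sorted contrasts; and voxels significant in the
first 10 s post-stimulus are partitioned by temporal-correlation k-means
into three networks -- DAS (early positive), TPN (late positive), DMN (late
negative).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import clusterstat

__all__ = [
    "BoldEpochSet",
    "ConjunctionMap",
    "NetworkPartition",
    "percent_change_epochs",
    "group_contrast_map",
    "conjunction_map",
    "exclusive_disjunction_map",
    "remove_eye_movement_signals",
    "select_network_voxels",
    "kmeans_networks",
    "roi_timecourse",
]

NETWORK_NAMES = ("DAS", "TPN", "DMN")


@dataclass
class BoldEpochSet:
    """Participant-level percent-change epochs: participants x voxels x time.

    The time axis spans the peri-event epoch (by default -20..+20 s on the
    TR grid) and includes 0; voxels are the flattened (C-order) grid.
    """

    percent_change: np.ndarray
    grid_dims: tuple[int, int, int]
    times: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        p, v, t = self.percent_change.shape
        if v != int(np.prod(self.grid_dims)):
            raise ValueError("voxel axis does not match grid_dims")
        if len(self.times) != t:
            raise ValueError("time axis does not match times")
        if not (self.times.min() <= 0 <= self.times.max()):
            raise ValueError("time grid must include 0")

    @property
    def n_participants(self) -> int:
        return self.percent_change.shape[0]


def percent_change_epochs(
    bold: np.ndarray,
    event_onsets,
    tr: float = 1.0,
    baseline_window: tuple[float, float] = (-2.0, 0.0),
    epoch_window: tuple[float, float] = (-20.0, 20.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked percent-change epochs from a 4-D scan (x, y, z, t).

    For each event and voxel: 100 * (signal - baseline mean) / baseline mean,
    with the baseline taken over ``baseline_window`` before the event.
    Voxels whose baseline mean is not positive in some epoch are masked out
    (returned ``voxel_ok`` False) with a warning.

    Returns (epochs (n_events, n_voxels, n_times), times, voxel_ok).
    """
    bold = np.asarray(bold, dtype=float)
    x, y, z, n_t = bold.shape
    flat = bold.reshape(-1, n_t)
    lo = int(round(epoch_window[0] / tr))
    hi = int(round(epoch_window[1] / tr))
    times = np.arange(lo, hi + 1) * tr
    b_lo = int(round(baseline_window[0] / tr))
    b_hi = int(round(baseline_window[1] / tr))
    epochs = []
    voxel_ok = np.ones(flat.shape[0], dtype=bool)
    for onset in np.atleast_1d(np.asarray(event_onsets, dtype=float)):
        c = int(round(onset / tr))
        if c + lo < 0 or c + hi >= n_t:
            raise ValueError("event closer than the epoch window to a scan edge")
        base = flat[:, c + b_lo : c + b_hi].mean(axis=1)
        bad = base <= 0
        if bad.any():
            voxel_ok &= ~bad
        safe = np.where(bad, 1.0, base)
        seg = flat[:, c + lo : c + hi + 1]
        epochs.append(100.0 * (seg - safe[:, None]) / safe[:, None])
    if not voxel_ok.all():
        warnings.warn(
            f"{int((~voxel_ok).sum())} voxels with non-positive baseline masked out"
        )
    return np.stack(epochs), times, voxel_ok


def group_contrast_map(
    set_perceived: BoldEpochSet,
    set_not_perceived: BoldEpochSet,
    config: clusterstat.ClusterTestConfig | None = None,
) -> clusterstat.ClusterTestResult:
    """Perceived minus not perceived spatiotemporal cluster test.

    Conditions must be paired across participants (same order).
    """
    a, b = set_perceived, set_not_perceived
    if a.percent_change.shape != b.percent_change.shape:
        raise ValueError("condition sets must be paired with matching shapes")
    if a.grid_dims != b.grid_dims:
        raise ValueError("grid mismatch")
    diff = a.percent_change - b.percent_change
    cube = clusterstat.DataCube(
        values=diff, times=a.times, space_shape=tuple(a.grid_dims)
    )
    return clusterstat.permutation_test(cube, config, mode="spatiotemporal")


# ---------------------------------------------------------------------------
# conjunction / disjunction


def _signed_masks(res: clusterstat.ClusterTestResult) -> tuple[np.ndarray, np.ndarray]:
    pos = res.significant_mask & (res.t_map > 0)
    neg = res.significant_mask & (res.t_map < 0)
    return pos, neg


@dataclass
class ConjunctionMap:
    """Voxel-time conjunction of two (or more) contrasts' significances.

    ``shared_increase`` / ``shared_decrease`` mark points significant with
    the same sign in every source; per-source signed masks are kept for
    disjunction queries.  ``*_any_time`` collapse the epoch axis (a voxel is
    marked if any sample is shared).
    """

    shared_increase: np.ndarray
    shared_decrease: np.ndarray
    source_masks: dict
    space_shape: tuple | None = None

    @property
    def shared_increase_any_time(self) -> np.ndarray:
        return self.shared_increase.any(axis=-1)

    @property
    def shared_decrease_any_time(self) -> np.ndarray:
        return self.shared_decrease.any(axis=-1)


def _check_same_grid(*results: clusterstat.ClusterTestResult) -> None:
    shapes = {r.t_map.shape for r in results}
    grids = {r.space_shape for r in results}
    if len(shapes) > 1 or len(grids) > 1:
        raise ValueError("contrasts are not on the same grid / time axis")


def conjunction_map(
    result_a: clusterstat.ClusterTestResult,
    result_b: clusterstat.ClusterTestResult,
) -> ConjunctionMap:
    """Voxel-time points significant in both contrasts with matching sign."""
    _check_same_grid(result_a, result_b)
    a_pos, a_neg = _signed_masks(result_a)
    b_pos, b_neg = _signed_masks(result_b)
    return ConjunctionMap(
        shared_increase=a_pos & b_pos,
        shared_decrease=a_neg & b_neg,
        source_masks={
            "A": {"increase": a_pos, "decrease": a_neg},
            "B": {"increase": b_pos, "decrease": b_neg},
        },
        space_shape=result_a.space_shape,
    )


def exclusive_disjunction_map(
    result_a: clusterstat.ClusterTestResult,
    result_b: clusterstat.ClusterTestResult,
) -> dict:
    """Voxel-time points significant only in A (and only in B), per sign."""
    _check_same_grid(result_a, result_b)
    a_pos, a_neg = _signed_masks(result_a)
    b_pos, b_neg = _signed_masks(result_b)
    return {
        "only_A": {"increase": a_pos & ~b_pos, "decrease": a_neg & ~b_neg},
        "only_B": {"increase": b_pos & ~a_pos, "decrease": b_neg & ~a_neg},
    }


def remove_eye_movement_signals(
    noreport_diff: np.ndarray,
    sorted_diffs: dict[str, np.ndarray],
    grid_dims: tuple[int, int, int],
    times: np.ndarray,
    config: clusterstat.ClusterTestConfig | None = None,
    noreport_result: clusterstat.ClusterTestResult | None = None,
) -> ConjunctionMap:
    """Remove pupil/blink/microsaccade-related signal from the no-report map.

    For each eye-movement modality, the paired contrast (no-report difference
    epochs minus that modality's high-vs-low sorted difference epochs) is
    tested; signal fully explained by the sorted modality cancels and drops
    out.  The final map is the conjunction, over the three modalities, of
    the no-report-greater significances, intersected with the no-report
    contrast's own significant mask (so the output is always a subset of the
    no-report map).

    ``noreport_diff`` and each sorted difference are participants x voxels x
    time percent-change arrays on one grid, paired by participant.
    """
    grid = tuple(grid_dims)
    if noreport_result is None:
        cube = clusterstat.DataCube(noreport_diff, times=times, space_shape=grid)
        noreport_result = clusterstat.permutation_test(
            cube, config, mode="spatiotemporal"
        )
    nr_pos, nr_neg = _signed_masks(noreport_result)
    keep_pos, keep_neg = nr_pos.copy(), nr_neg.copy()
    source_masks = {"no_report": {"increase": nr_pos, "decrease": nr_neg}}
    for name, sdiff in sorted_diffs.items():
        if sdiff.shape != noreport_diff.shape:
            raise ValueError(f"sorted diff {name!r} not on the no-report grid")
        cube = clusterstat.DataCube(
            noreport_diff - sdiff, times=times, space_shape=grid
        )
        res = clusterstat.permutation_test(cube, config, mode="spatiotemporal")
        pos, neg = _signed_masks(res)
        keep_pos &= pos
        keep_neg &= neg
        source_masks[name] = {"increase": pos, "decrease": neg}
    return ConjunctionMap(
        shared_increase=keep_pos,
        shared_decrease=keep_neg,
        source_masks=source_masks,
        space_shape=grid,
    )


# ---------------------------------------------------------------------------
# network partitioning


def select_network_voxels(
    result: clusterstat.ClusterTestResult,
    window: tuple[float, float] = (0.0, 10.0),
) -> np.ndarray:
    """Voxels significant for at least one sample in (0, 10] s post-stimulus.

    Returns a boolean array over the flattened voxel axis.
    """
    if result.times is None:
        raise ValueError("result lacks a time axis")
    t = np.asarray(result.times)
    if t.max() < window[1]:
        raise ValueError("result's time axis does not cover the selection window")
    mask = (t > window[0]) & (t <= window[1])
    return result.significant_mask[:, mask].any(axis=1)


@dataclass
class NetworkPartition:
    """k-means network labels over the selected voxels.

    ``labels`` maps each selected voxel (by flat grid index) to a network
    name; per-cluster mean timecourses cover the clustering window.
    """

    voxel_indices: np.ndarray
    labels: np.ndarray  # array of str, aligned with voxel_indices
    cluster_timecourses: dict[str, np.ndarray]
    times: np.ndarray
    inertia: float
    k: int = 3

    def label_image(self, grid_dims) -> np.ndarray:
        """Integer label volume: 0 unlabeled, 1 DAS, 2 TPN, 3 DMN."""
        out = np.zeros(int(np.prod(grid_dims)), dtype=np.int16)
        code = {name: i + 1 for i, name in enumerate(NETWORK_NAMES)}
        for idx, lab in zip(self.voxel_indices, self.labels):
            out[idx] = code[str(lab)]
        return out.reshape(grid_dims)


def _label_clusters_by_dynamics(
    centers: np.ndarray, times: np.ndarray, early_late_split: float = 4.0
) -> list[str]:
    """Assign DAS / TPN / DMN by each cluster's mean timecourse shape:
    negative-dominated trough -> DMN; positive peak at <= 4 s -> DAS;
    later positive peak -> TPN."""
    assigned: dict[int, str] = {}
    for i in range(len(centers)):
        c = centers[i]
        if abs(c.min()) > abs(c.max()):
            assigned[i] = "DMN"
        else:
            peak_t = times[int(np.argmax(c))]
            assigned[i] = "DAS" if peak_t <= early_late_split else "TPN"
    if len(set(assigned.values())) < len(centers):
        warnings.warn(
            "cluster dynamics do not separate into DAS/TPN/DMN; "
            "labels assigned by rule may repeat"
        )
    return [assigned[i] for i in range(len(centers))]


def kmeans_networks(
    timecourses: np.ndarray,
    times: np.ndarray,
    voxel_indices: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 100,
) -> NetworkPartition:
    """Temporal-correlation k-means partition of voxel timecourses.

    ``timecourses`` is (n_voxels, n_times): the perceived-minus-not-perceived
    percent-change signal over the first 10 s post-stimulus, averaged across
    participants.  Rows are z-scored so Euclidean k-means is equivalent to
    clustering with the 1 - Pearson-correlation distance; the best of
    ``n_restarts`` seeded restarts by within-cluster dispersion is kept.
    Cluster labels follow the dynamics rule (positive early peak -> DAS,
    positive late peak -> TPN, negative trough -> DMN); the rule is defined
    for k = 3 only.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < k:
        raise ValueError("need at least k voxel timecourses")
    sd = tc.std(axis=1)
    if np.unique(tc[sd > 0], axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct timecourses")
    z = (tc - tc.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
    idx = km.fit_predict(z)
    centers = np.stack([tc[idx == j].mean(axis=0) for j in range(k)])
    if k == 3:
        names = _label_clusters_by_dynamics(centers, np.asarray(times))
    else:
        names = [f"cluster{j}" for j in range(k)]
    if voxel_indices is None:
        voxel_indices = np.arange(tc.shape[0])
    return NetworkPartition(
        voxel_indices=np.asarray(voxel_indices),
        labels=np.asarray([names[j] for j in idx], dtype=object),
        cluster_timecourses={
            name: centers[j] for j, name in enumerate(names)
        },
        times=np.asarray(times),
        inertia=float(km.inertia_),
        k=k,
    )


def roi_timecourse(
    epochs: BoldEpochSet | np.ndarray,
    roi_mask: np.ndarray,
    partition: NetworkPartition | None = None,
) -> dict:
    """Mean percent-change timecourse over an ROI, with the percentage of
    the ROI's network-labeled voxels belonging to each network.

    ``roi_mask`` is boolean over the flattened voxel axis (or the grid).
    """
    roi = np.asarray(roi_mask).ravel().astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    data = epochs.percent_change if isinstance(epochs, BoldEpochSet) else epochs
    if data.ndim == 2:
        data = data[None]
    mean_tc = data[:, roi, :].mean(axis=(0, 1))
    out = {"timecourse": mean_tc, "n_voxels": int(roi.sum())}
    if partition is not None:
        in_roi = roi[partition.voxel_indices]
        labeled = partition.labels[in_roi]
        total = len(labeled)
        out["network_fractions"] = {
            name: (100.0 * float(np.mean(labeled == name)) if total else float("nan"))
            for name in NETWORK_NAMES
        }
    return out
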