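"""Model-free cluster-based permutation statistics.

One-sample (sign-flip) cluster-based permutation tests for participant-level
condition-difference data, in two adjacency modes:

``temporal_only``
    clusters are runs of contiguous supra-threshold time samples within each
    signal (used for pupil/blink/microsaccade rates, ROI and channel
    timecourses);
``spatiotemporal``
    clusters connect across space (6-connected voxel grids, or an explicit
    channel neighbor graph) and across adjacent time samples.

The cluster-forming statistic is the cluster *mass*, the sum of point-level
one-sample t values over a connected set of like-signed supra-threshold
points.  The null distribution is the maximum absolute cluster mass over
clusters in each sign-flip permutation (pooling signs, i.e. two-tailed
family-wise control).  Also provides Wilcoxon rank-sum and Holm-Bonferroni
utilities used by the latency analyses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DataCube",
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "compute_group_tmap",
    "form_clusters",
    "permutation_test",
    "holm_bonferroni",
    "wilcoxon_rank_sum",
]

AdjacencyMode = Literal["temporal_only", "spatiotemporal"]


@dataclass
class DataCube:
    """Participants x space x time data for a one-sample cluster test.

    ``values`` has shape (n_participants, n_space, n_time); a plain
    timecourse uses n_space == 1.  For voxel grids set ``space_shape`` (the
    flattened C-order grid dims); for channel data pass ``adjacency``, a list
    of neighbor-index lists (symmetric, irreflexive).
    """

    values: np.ndarray
    times: np.ndarray | None = None
    space_shape: tuple[int, ...] | None = None
    adjacency: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # participants x time
            self.values = self.values[:, None, :]
        if self.values.ndim != 3:
            raise ValueError("values must be (participants, space, time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.space_shape is not None:
            if int(np.prod(self.space_shape)) != self.n_space:
                raise ValueError("space_shape does not match flattened space axis")
        if self.adjacency is not None:
            if len(self.adjacency) != self.n_space:
                raise ValueError("adjacency length must equal n_space")
            for i, nbrs in enumerate(self.adjacency):
                for j in nbrs:
                    if j == i:
                        raise ValueError("adjacency must be irreflexive")
                    if i not in self.adjacency[j]:
                        raise ValueError("adjacency must be symmetric")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_space(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]


@dataclass
class ClusterTestConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    cluster_forming_p: float = 0.05  # two-tailed point-level threshold
    statistic: Literal["mass", "size"] = "mass"
    tail: Literal["two"] = "two"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.cluster_forming_p < 1:
            raise ValueError("cluster_forming_p must be in (0, 1)")


@dataclass
class Cluster:
    indices: np.ndarray  # flat indices into the (space, time) map
    mass: float
    sign: int
    p_value: float = float("nan")

    @property
    def size(self) -> int:
        return int(self.indices.size)


@dataclass
class ClusterTestResult:
    t_map: np.ndarray  # (n_space, n_time)
    clusters: list[Cluster]
    significant_mask: np.ndarray  # bool (n_space, n_time)
    null_max_mass: np.ndarray
    alpha: float
    threshold_t: float
    times: np.ndarray | None = None
    space_shape: tuple[int, ...] | None = None

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha]

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "threshold_t": self.threshold_t,
            "n_clusters": len(self.clusters),
            "clusters": [
                {
                    "size": c.size,
                    "mass": c.mass,
                    "sign": c.sign,
                    "p_value": c.p_value,
                }
                for c in self.clusters
            ],
        }


def _tmap_from_moments(mean: np.ndarray, msq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t from the first two moments; zero-variance points -> t=0."""
    var = (msq - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var <= 1e-300, 0.0, t)


def compute_group_tmap(cube: DataCube) -> np.ndarray:
    """Pointwise one-sample t of participant values against zero.

    Points with zero variance across participants get t = 0 with a warning
    (a degenerate point carries no evidence either way).
    """
    x = cube.values
    n = cube.n_participants
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = x.mean(axis=0)
    msq = (x**2).mean(axis=0)
    var = (msq - mean**2) * (n / (n - 1))
    if np.any((var <= 1e-300) & (np.abs(mean) > 0)):
        warnings.warn("zero-variance points encountered; their t set to 0")
    return _tmap_from_moments(mean, msq, n)


# ---------------------------------------------------------------------------
# cluster formation


def _grid_structure(ndim: int) -> np.ndarray:
    # faces-only connectivity: 6-connected in 3-D space, +/-1 in time
    return ndimage.generate_binary_structure(ndim, 1)


def _clusters_from_labels(
    t_map: np.ndarray, labeled: np.ndarray, n_lab: int, sign: int
) -> list[Cluster]:
    out: list[Cluster] = []
    if n_lab == 0:
        return out
    flat_lab = labeled.ravel()
    order = np.argsort(flat_lab, kind="stable")
    sorted_lab = flat_lab[order]
    starts = np.searchsorted(sorted_lab, np.arange(1, n_lab + 1), side="left")
    ends = np.searchsorted(sorted_lab, np.arange(1, n_lab + 1), side="right")
    flat_t = t_map.ravel()
    for s, e in zip(starts, ends):
        idx = np.sort(order[s:e])
        out.append(Cluster(indices=idx, mass=float(flat_t[idx].sum()), sign=sign))
    return out


def _label_graph(mask: np.ndarray, adjacency: list[list[int]]) -> list[np.ndarray]:
    """Connected components of supra-threshold (space, time) points under a
    channel neighbor graph plus +/-1 temporal adjacency.  Union-find."""
    n_space, n_time = mask.shape
    pts = np.flatnonzero(mask.ravel())
    if pts.size == 0:
        return []
    pos = {int(p): i for i, p in enumerate(pts)}
    parent = list(range(pts.size))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    flat = mask.ravel()
    for p in pts:
        s, t = divmod(int(p), n_time)
        if t + 1 < n_time and flat[p + 1]:
            union(pos[int(p)], pos[int(p + 1)])
        for nb in adjacency[s]:
            q = nb * n_time + t
            if flat[q] and q > p:
                union(pos[int(p)], pos[int(q)])
    comps: dict[int, list[int]] = {}
    for i, p in enumerate(pts):
        comps.setdefault(find(i), []).append(int(p))
    return [np.array(sorted(v)) for v in comps.values()]


def form_clusters(
    t_map: np.ndarray,
    threshold_t: float,
    mode: AdjacencyMode = "temporal_only",
    space_shape: tuple[int, ...] | None = None,
    adjacency: list[list[int]] | None = None,
) -> list[Cluster]:
    """Group like-signed supra-threshold points into connected clusters.

    ``t_map`` is (n_space, n_time).  Mass is the sum of member t values.
    """
    if threshold_t <= 0:
        raise ValueError("threshold_t must be positive")
    t_map = np.atleast_2d(np.asarray(t_map, dtype=float))
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = sign * t_map > threshold_t
        if not mask.any():
            continue
        if mode == "temporal_only":
            structure = np.zeros((3, 3), dtype=bool)
            structure[1, :] = True  # adjacency along time only
            labeled, n_lab = ndimage.label(mask, structure=structure)
            clusters.extend(_clusters_from_labels(t_map, labeled, n_lab, sign))
        elif mode == "spatiotemporal":
            if space_shape is not None:
                shaped = mask.reshape(*space_shape, t_map.shape[-1])
                labeled, n_lab = ndimage.label(
                    shaped, structure=_grid_structure(shaped.ndim)
                )
                clusters.extend(
                    _clusters_from_labels(
                        t_map, labeled.reshape(t_map.shape), n_lab, sign
                    )
                )
            elif adjacency is not None:
                for idx in _label_graph(mask, adjacency):
                    clusters.append(
                        Cluster(
                            indices=idx,
                            mass=float(t_map.ravel()[idx].sum()),
                            sign=sign,
                        )
                    )
            else:
                raise ValueError(
                    "spatiotemporal mode needs space_shape or adjacency"
                )
        else:
            raise ValueError(f"unknown adjacency mode: {mode}")
    return clusters


def _max_cluster_stat(
    t_map: np.ndarray,
    threshold_t: float,
    mode: AdjacencyMode,
    space_shape,
    adjacency,
    statistic: str,
) -> float:
    """Max |cluster statistic| over both signs for one permutation's t map."""
    best = 0.0
    for c in form_clusters(t_map, threshold_t, mode, space_shape, adjacency):
        val = abs(c.mass) if statistic == "mass" else float(c.size)
        if val > best:
            best = val
    return best


def _sign_matrix(n: int, config: ClusterTestConfig) -> tuple[np.ndarray, bool]:
    """Permutation sign-flip matrix; exhaustive if 2**n <= n_perm."""
    if 2**n <= config.n_perm:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        return 1.0 - 2.0 * bits, True
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_perm, n))
    return signs, False


def permutation_test(
    cube: DataCube,
    config: ClusterTestConfig | None = None,
    mode: AdjacencyMode | None = None,
) -> ClusterTestResult:
    """Sign-flip cluster-based permutation test on a DataCube.

    The null distribution is the maximum absolute cluster mass (or size) per
    permutation, pooled over both signs; for a sampled null, cluster
    p = (1 + #{null >= observed}) / (n_perm + 1), so p is never exactly 0.
    When 2**N <= n_perm the full set of sign flips is enumerated instead and
    p = #{null >= observed} / 2**N (the identity flip is one of them).
    """
    if config is None:
        config = ClusterTestConfig()
    if mode is None:
        mode = (
            "temporal_only"
            if (cube.space_shape is None and cube.adjacency is None)
            else "spatiotemporal"
        )
    n = cube.n_participants
    if n < 2:
        raise ValueError("need at least 2 participants")
    df = n - 1
    threshold_t = float(stats.t.ppf(1 - config.cluster_forming_p / 2, df))

    x = cube.values.reshape(n, -1)
    msq = (x**2).mean(axis=0)
    map_shape = (cube.n_space, cube.n_time)

    t_obs = compute_group_tmap(cube)
    observed = form_clusters(
        t_obs, threshold_t, mode, cube.space_shape, cube.adjacency
    )

    signs, exhaustive = _sign_matrix(n, config)
    n_draws = signs.shape[0]
    null = np.empty(n_draws)
    chunk = max(1, int(2e7 // max(x.size // n * 8, 1)))  # bound scratch memory
    for start in range(0, n_draws, chunk):
        s = signs[start : start + chunk]
        mean = s @ x / n
        t_perm = _tmap_from_moments(mean, msq, n)
        for i in range(s.shape[0]):
            null[start + i] = _max_cluster_stat(
                t_perm[i].reshape(map_shape),
                threshold_t,
                mode,
                cube.space_shape,
                cube.adjacency,
                config.statistic,
            )

    for c in observed:
        val = abs(c.mass) if config.statistic == "mass" else float(c.size)
        ge = int(np.count_nonzero(null >= val))
        if exhaustive:
            c.p_value = ge / n_draws
        else:
            c.p_value = (1 + ge) / (n_draws + 1)

    sig = np.zeros(map_shape, dtype=bool)
    for c in observed:
        if c.p_value <= config.alpha:
            sig.ravel()[c.indices] = True
    return ClusterTestResult(
        t_map=t_obs,
        clusters=observed,
        significant_mask=sig,
        null_max_mass=null,
        alpha=config.alpha,
        threshold_t=threshold_t,
        times=cube.times,
        space_shape=cube.space_shape,
    )


# ---------------------------------------------------------------------------
# latency-analysis utilities


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    return multipletests(p, method="holm")[1]


def wilcoxon_rank_sum(x, y, tail: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Exact enumeration for combined n <= 12 without ties; normal approximation
    with tie correction otherwise.  Returns (rank-sum of x, p value).  If every
    value in both samples is identical, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    w = float(stats.rankdata(combined)[: x.size].sum())
    if np.all(combined == combined[0]):
        return w, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=tail, method=method)
    return w, float(res.pvalue)
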