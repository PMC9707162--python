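"""Independent reference implementations used only by the tests.

These deliberately use naive algorithms (flood fill, explicit enumeration,
direct Monte-Carlo sampling from the generative model) so that they share no
code path with the package implementations they check.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def flood_fill_clusters(mask: np.ndarray, connect_time_axis: bool = True):
    """Connected components of a boolean array via BFS flood fill.

    Adjacency is +/-1 along each axis (faces only).  Returns a list of sets
    of flat indices.
    """
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        comp = set()
        q = deque([start])
        visited[start] = True
        while q:
            pt = q.popleft()
            comp.add(int(np.ravel_multi_index(pt, mask.shape)))
            for ax in range(mask.ndim):
                if not connect_time_axis and ax == mask.ndim - 1:
                    continue
                for d in (-1, 1):
                    nb = list(pt)
                    nb[ax] += d
                    if 0 <= nb[ax] < mask.shape[ax]:
                        nb = tuple(nb)
                        if mask[nb] and not visited[nb]:
                            visited[nb] = True
                            q.append(nb)
        comps.append(comp)
    return comps


def exhaustive_signflip_null(values: np.ndarray, threshold_t: float):
    """Max |cluster mass| over all 2^N sign flips of a participants x time
    array, computed with naive per-flip loops (1-D temporal adjacency)."""
    n = values.shape[0]
    out = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = np.asarray(signs)[:, None] * values
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        best = 0.0
        for sign in (1, -1):
            run = 0.0
            active = False
            for v in t:
                if sign * v > threshold_t:
                    run += v
                    active = True
                else:
                    if active:
                        best = max(best, abs(run))
                    run, active = 0.0, False
            if active:
                best = max(best, abs(run))
        out.append(best)
    return np.asarray(out)


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    nx = len(x)
    w_obs = ranks[:nx].sum()
    ws = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    ws = np.asarray(ws)
    mean_w = ws.mean()
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return float(p)


def holm_by_hand(p_values):
    """Step-down Holm adjustment computed directly from the definition."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def bayes_rate_eye_features(params, n_baseline_s=0.5, n_mc=20000, seed=0):
    """Monte-Carlo Bayes balanced accuracy for the eye-feature generative
    model, computed from the model's closed-form feature distributions.

    The oracle draws features directly from their known distributions --
    Gaussian pupil window means (white + moving-average drift noise,
    covariance assembled from the MA representation, with the template mean
    added for perceived trials) and Poisson blink/microsaccade counts with
    the known modulated rates -- and classifies with the exact
    log-likelihood ratio.  It never touches the package's rendering,
    detection, or classification code.
    """
    from noreport.synth.eye import pupil_impulse_response

    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    windows = [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)]
    base_win = (-n_baseline_s, 0.0)

    # linear functionals over samples: window means minus baseline mean
    half = 6.0
    n = int(round(2 * half * fs))
    t = (np.arange(n) - n // 2) / fs
    funcs = []
    bmask = (t >= base_win[0]) & (t < base_win[1])
    for lo, hi in windows:
        w = np.zeros(n)
        m = (t > lo) & (t <= hi)
        w[m] = 1.0 / m.sum()
        w[bmask] -= 1.0 / bmask.sum()
        funcs.append(w)
    W = np.stack(funcs)  # (3, n)

    # sample covariance: white + moving average drift (band covariance)
    L = max(1, int(round(params.drift_window * fs)))
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    # MA(L) of unit white noise scaled to drift_sd has cov sd^2*(1-|lag|/L)+
    cov_drift = params.drift_sd**2 * np.clip(1 - lags / L, 0, None)
    cov = cov_drift + params.noise_sd**2 * np.eye(n)
    feat_cov = W @ cov @ W.T  # (3, 3)

    kernel = params.pupil_dilation_amp * pupil_impulse_response(
        t, params.pupil_peak_latency, params.pupil_gamma_shape
    )
    mu1 = W @ kernel  # perceived mean shift
    mu0 = np.zeros_like(mu1)

    # Poisson count rates in the count windows
    def rates(perceived):
        blink = []
        for lo, hi in [(0.0, 1.0), (1.0, 2.0)]:
            lam = 0.0
            for edge in np.linspace(lo, hi, 101)[:-1]:
                g0, g1 = params.blink_gain_window
                gain = params.blink_rate_gain_perceived if (perceived and g0 <= edge < g1) else 1.0
                lam += params.blink_rate_base * gain * (hi - lo) / 100
            blink.append(lam)
        ms = []
        for lo, hi in [(0.0, 0.5), (0.5, 1.0)]:
            lam = 0.0
            for edge in np.linspace(lo, hi, 101)[:-1]:
                s0, s1 = params.msacc_suppression_window
                f = params.msacc_suppression_factor if (perceived and s0 <= edge < s1) else 1.0
                lam += params.msacc_rate_base * f * (hi - lo) / 100
            ms.append(lam)
        return np.array(blink + ms)

    lam1, lam0 = rates(True), rates(False)
    prec = np.linalg.inv(feat_cov)

    def llr(pupil_feats, counts):
        g1 = -0.5 * np.einsum("ni,ij,nj->n", pupil_feats - mu1, prec, pupil_feats - mu1)
        g0 = -0.5 * np.einsum("ni,ij,nj->n", pupil_feats - mu0, prec, pupil_feats - mu0)
        pois = counts @ np.log(lam1 / lam0) - (lam1 - lam0).sum()
        return (g1 - g0) + pois

    chol = np.linalg.cholesky(feat_cov)
    correct = []
    for label, mu, lam in ((1, mu1, lam1), (0, mu0, lam0)):
        pupil = mu + rng.standard_normal((n_mc, 3)) @ chol.T
        counts = rng.poisson(lam, size=(n_mc, 4))
        pred = llr(pupil, counts) > 0
        correct.append(np.mean(pred == bool(label)))
    return 0.5 * (correct[0] + correct[1])
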