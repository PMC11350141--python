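"""Functional-connectivity graphs on block-wise HbT correlations.

For each 72-s n-back block, Pearson correlations between all retained
channel pairs are thresholded against circular-shift surrogate nulls
(autocorrelation preserved, cross-correlation destroyed): an edge
survives only with significant (p < alpha), positive r.  Negative
coefficients are zeroed.  The surviving matrix r* feeds the normalized
binary and weighted node-degree metrics:

* D_i  — number of edges at node i; global D-bar = mean_i D_i / (N-1);
* wD_i — summed edge weight at node i; normalized by (N-1) x the maximum
  edge weight observed in that graph (so values lie in [0, 1]);
* LDLPFC variants average the three LDLPFC channels' normalized values;
* task-averaged variants average the per-block values over conditions.

Fisher averaging (atanh before the mean, tanh back) is used whenever
matrices are averaged across blocks or subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TaskDesign
from .montage import Montage
from .preprocess import ChromophoreSeries

__all__ = [
    "GraphMetrics",
    "block_correlation",
    "surrogate_threshold",
    "graph_metrics",
    "task_average",
    "fisher_average",
    "subject_connectivity",
]


@dataclass
class GraphMetrics:
    """Binary and weighted degree metrics of one thresholded graph."""

    labels: tuple[str, ...]
    degree: np.ndarray  # D_i, counts
    strength: np.ndarray  # wD_i, summed weights
    d_bar: float
    wd_bar: float
    d_ldp: float
    wd_ldp: float

    def scalars(self) -> dict[str, float]:
        return {
            "d_bar": self.d_bar, "wd_bar": self.wd_bar,
            "d_ldp": self.d_ldp, "wd_ldp": self.wd_ldp,
        }


def _block_slice(design: TaskDesign, condition: str, fs_hz: float, n_time: int):
    blk = design.block(condition)
    i0 = int(round(blk.onset_s * fs_hz))
    i1 = int(round((blk.onset_s + blk.duration_s) * fs_hz))
    if i1 > n_time:
        raise ValueError(
            f"block {condition} ends beyond the record ({i1} > {n_time} samples)"
        )
    return slice(i0, i1)


def block_correlation(
    hbt: np.ndarray,
    design: TaskDesign,
    condition: str,
    fs_hz: float,
) -> np.ndarray:
    """Pearson r over one block window for all channel pairs."""
    hbt = np.atleast_2d(np.asarray(hbt, dtype=float))
    window = _block_slice(design, condition, fs_hz, hbt.shape[-1])
    seg = hbt[:, window]
    return np.corrcoef(seg)


def surrogate_threshold(
    r: np.ndarray,
    hbt_block: np.ndarray,
    alpha: float = 0.05,
    n_surr: int = 200,
    seed: int = 0,
    method: str = "circular",
    full_series: np.ndarray | None = None,
    window_start: int = 0,
) -> np.ndarray:
    """Keep positive, surrogate-significant correlations; zero the rest.

    ``circular`` (default): the null for each pair is the set of Pearson
    correlations between one channel's block window and random circular
    time shifts of the other channel, which preserves each channel's
    autocorrelation while destroying any cross-correlation.  When the
    surrounding session is available (``full_series`` with the block's
    ``window_start``), shifts are drawn over the whole session so the
    wrap discontinuity almost never falls inside the correlation window;
    otherwise the block itself is wrapped.  One-sided
    p = (1 + #{r_surr >= r_obs}) / (n_surr + 1).

    ``parametric``: the t test of a Pearson correlation (n - 2 dof).
    """
    r = np.asarray(r, dtype=float)
    x = np.atleast_2d(np.asarray(hbt_block, dtype=float))
    n_ch, n = x.shape
    r_star = np.zeros_like(r)
    if method == "parametric":
        from scipy import stats as sps

        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-15))
        p = sps.t.sf(t, df=n - 2)  # one-sided, positive tail
    elif method == "circular":
        if n_surr < int(np.ceil(1.0 / alpha)) - 1:
            raise ValueError(
                f"n_surr={n_surr} cannot resolve p < {alpha}; need >= "
                f"{int(np.ceil(1.0 / alpha)) - 1}"
            )
        full = x if full_series is None else np.atleast_2d(
            np.asarray(full_series, dtype=float)
        )
        n_full = full.shape[1]
        z = x - x.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = z / sd
        rng = np.random.default_rng(seed)
        candidates = np.arange(1, n_full)
        if n_full > n:
            # keep only shifts whose window is a contiguous session
            # segment: windows spanning the wrap point contain an
            # artificial discontinuity that narrows the null
            start = (window_start + candidates) % n_full
            candidates = candidates[start + n <= n_full]
            if candidates.size < 2 * int(np.ceil(1.0 / alpha)):
                candidates = np.arange(1, n_full)
        lags = rng.choice(candidates, size=n_surr, replace=True)
        idx = (window_start + np.arange(n)[None, :] + lags[:, None]) % n_full
        p = np.ones_like(r)
        for j in range(1, n_ch):
            S = full[j][idx]  # (n_surr, n) shifted windows of channel j
            S = S - S.mean(axis=1, keepdims=True)
            ssd = S.std(axis=1, keepdims=True)
            ssd[ssd == 0] = 1.0
            surr = (S / ssd) @ z[:j].T / n  # (n_surr, j)
            exceed = (surr >= r[j, :j][None, :]).sum(axis=0)
            p[j, :j] = p[:j, j] = (1.0 + exceed) / (n_surr + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    keep = (p < alpha) & (r > 0)
    r_star[keep] = r[keep]
    np.fill_diagonal(r_star, 0.0)
    return r_star


def graph_metrics(
    r_star: np.ndarray,
    labels: tuple[str, ...] | Montage,
    ldlpfc_labels: tuple[str, ...] | None = None,
    weighted_normalization: str = "max_weight",
) -> GraphMetrics:
    """Normalized binary and weighted node-degree metrics.

    ``weighted_normalization`` realizes "adjusted relative to the maximum
    connection strength": ``max_weight`` divides node strength by
    (N-1) x the graph's maximum edge weight (default); ``possible``
    divides by (N-1) only (weights are already in [0, 1]).
    """
    if isinstance(labels, Montage):
        ldlpfc_labels = ldlpfc_labels or labels.ldlpfc_labels
        labels = tuple(labels.labels)
    if ldlpfc_labels is None:
        ldlpfc_labels = ()
    A = np.asarray(r_star, dtype=float)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if len(labels) != n:
        raise ValueError("one label per node required")
    degree = (A > 0).sum(axis=1)
    strength = A.sum(axis=1)
    norm_deg = degree / (n - 1)
    max_w = A.max()
    if weighted_normalization == "max_weight":
        denom = (n - 1) * max_w if max_w > 0 else 1.0
    elif weighted_normalization == "possible":
        denom = float(n - 1)
    else:
        raise ValueError(f"unknown normalization {weighted_normalization!r}")
    norm_strength = strength / denom
    ldl_idx = [labels.index(l) for l in ldlpfc_labels if l in labels]
    d_ldp = float(norm_deg[ldl_idx].mean()) if ldl_idx else 0.0
    wd_ldp = float(norm_strength[ldl_idx].mean()) if ldl_idx else 0.0
    return GraphMetrics(
        labels=tuple(labels), degree=degree, strength=strength,
        d_bar=float(norm_deg.mean()), wd_bar=float(norm_strength.mean()),
        d_ldp=d_ldp, wd_ldp=wd_ldp,
    )


def task_average(metrics_by_block: dict[str, GraphMetrics | dict]) -> dict[str, float]:
    """Arithmetic mean over available block conditions of each normalized
    scalar metric (available-mean convention for missing blocks)."""
    if not metrics_by_block:
        raise ValueError("need at least one block")
    rows = [
        m.scalars() if isinstance(m, GraphMetrics) else dict(m)
        for m in metrics_by_block.values()
    ]
    keys = rows[0].keys()
    return {k: float(np.mean([r[k] for r in rows])) for k in keys}


def fisher_average(matrices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean of atanh(r*) across graphs, plus the tanh
    back-transform.  Matrices must share the node set."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices must share the node set")
    z = np.arctanh(np.clip(np.stack(mats), -1 + 1e-12, 1 - 1e-12))
    z_mean = z.mean(axis=0)
    return z_mean, np.tanh(z_mean)


def subject_connectivity(
    series: ChromophoreSeries,
    design: TaskDesign,
    montage: Montage,
    alpha: float = 0.05,
    n_surr: int = 200,
    seed: int = 0,
    method: str = "circular",
) -> tuple[dict[str, np.ndarray], dict[str, GraphMetrics], dict[str, float]]:
    """Per-block thresholded graphs, their metrics, and the task averages."""
    if series.hbt is None:
        raise ValueError("FC-branch series with HbT required")
    graphs: dict[str, np.ndarray] = {}
    metrics: dict[str, GraphMetrics] = {}
    for k, blk in enumerate(design.blocks):
        window = _block_slice(design, blk.condition, series.fs_hz, series.hbt.shape[-1])
        seg = series.hbt[:, window]
        r = np.corrcoef(seg)
        r_star = surrogate_threshold(
            r, seg, alpha=alpha, n_surr=n_surr, seed=seed + k, method=method,
            full_series=series.hbt, window_start=window.start,
        )
        graphs[blk.condition] = r_star
        metrics[blk.condition] = graph_metrics(r_star, montage)
    return graphs, metrics, task_average(metrics)
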