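"""Recurring FNC states by exemplar-initialized k-means with Manhattan distance.

Clustering follows the two-stage convention: an initial k-means (L1
distance, componentwise-median centroid update — i.e. k-medians) is run
many times on high-variance "exemplar" windows, and the best solution
initializes a single pass over all windows.  The number of states is
chosen by the elbow of the cluster validity index (mean within-cluster
distance over mean between-centroid distance) across candidate k.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import FNCVectorSet, StateSequence, WindowedFNC, vec_upper

logger = logging.getLogger(__name__)


@dataclass
class StateModel:
    """Fitted centroids (k x E) with the L1 nearest-centroid assignment rule."""

    centroids: np.ndarray
    k: int
    assignment_metric: str = "cityblock"
    cost: float = np.nan
    cost_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")


@dataclass
class ClusterQuality:
    k_candidates: list[int]
    validity_index: np.ndarray
    chosen_k: int
    models: dict[int, StateModel] = field(default_factory=dict)


def pool_windows(wfncs: list[WindowedFNC]) -> FNCVectorSet:
    """Stack all runs' window z-matrices into an N x E edge-vector set with provenance."""
    if not wfncs:
        raise ValueError("no windowed FNC inputs")
    c = wfncs[0].n_components
    vectors = np.concatenate([vec_upper(w.z) for w in wfncs], axis=0)
    prov = pd.DataFrame(
        {
            "subject": np.concatenate([[w.subject_id] * w.n_windows for w in wfncs]),
            "condition": np.concatenate([[w.condition] * w.n_windows for w in wfncs]),
            "window": np.concatenate([np.arange(w.n_windows) for w in wfncs]),
        }
    )
    return FNCVectorSet(vectors=vectors, provenance=prov, n_components=c)


def _local_maxima(series: np.ndarray) -> np.ndarray:
    """Indices of local maxima; endpoints qualify against their single neighbor.

    Plateau ties break toward the earlier window: index i is selected when
    it strictly exceeds its left neighbor (or is the first window) and is
    at least as large as its right neighbor (or is the last window).
    """
    n = len(series)
    if n == 1:
        return np.array([0])
    sel = []
    for i in range(n):
        left_ok = i == 0 or series[i] > series[i - 1]
        right_ok = i == n - 1 or series[i] >= series[i + 1]
        if left_ok and right_ok:
            sel.append(i)
    if not sel:  # e.g. monotone decreasing after a flat start
        sel = [int(np.argmax(series))]
    return np.array(sel)


def select_exemplars(wfncs: list[WindowedFNC]) -> FNCVectorSet:
    """High-variance windows per run: local maxima of the per-window edge variance."""
    if not wfncs:
        raise ValueError("no windowed FNC inputs")
    c = wfncs[0].n_components
    chunks, subj, cond, widx = [], [], [], []
    for w in wfncs:
        vecs = vec_upper(w.z)
        if vecs.shape[0] < 3:
            warnings.warn(
                f"run {w.subject_id}/{w.condition} has fewer than 3 windows; keeping all",
                stacklevel=2,
            )
            idx = np.arange(vecs.shape[0])
        else:
            variance = vecs.var(axis=1)
            idx = _local_maxima(variance)
        chunks.append(vecs[idx])
        subj.extend([w.subject_id] * len(idx))
        cond.extend([w.condition] * len(idx))
        widx.extend(idx.tolist())
    return FNCVectorSet(
        vectors=np.concatenate(chunks, axis=0),
        provenance=pd.DataFrame({"subject": subj, "condition": cond, "window": widx}),
        n_components=c,
    )


def _l1_cost(x: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    d = cdist(x, centroids, metric="cityblock")
    labels = np.argmin(d, axis=1)
    return labels, float(d[np.arange(len(x)), labels].sum())


def _lloyd_l1(
    x: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """L1 Lloyd iterations with median updates and empty-cluster repair."""
    k = centroids.shape[0]
    centroids = centroids.copy()
    labels, cost = _l1_cost(x, centroids)
    trace = [cost]
    for _ in range(max_iter):
        for j in range(k):
            members = x[labels == j]
            if len(members) > 0:
                centroids[j] = np.median(members, axis=0)
            else:  # split the largest cluster: farthest member becomes the new centroid
                sizes = np.bincount(labels, minlength=k)
                big = int(np.argmax(sizes))
                members_big = np.flatnonzero(labels == big)
                d_big = np.abs(x[members_big] - centroids[big]).sum(axis=1)
                centroids[j] = x[members_big[np.argmax(d_big)]]
        new_labels, new_cost = _l1_cost(x, centroids)
        trace.append(new_cost)
        if np.array_equal(new_labels, labels):
            labels, cost = new_labels, new_cost
            break
        labels, cost = new_labels, new_cost
    return labels, centroids, cost, trace


def _distinct_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Choose k distinct data points as initial centroids."""
    n = len(x)
    for _ in range(100):
        idx = rng.choice(n, size=k, replace=False)
        cand = x[idx]
        if len(np.unique(cand, axis=0)) == k:
            return cand.copy()
    uniq = np.unique(x, axis=0)
    if len(uniq) < k:
        raise ValueError("fewer than k distinct points; cannot initialize")
    return uniq[rng.choice(len(uniq), size=k, replace=False)].copy()


def kmeans_manhattan(
    x: np.ndarray | FNCVectorSet,
    k: int,
    n_replicates: int = 10,
    max_iter: int = 100,
    seed: int | np.random.Generator | None = None,
) -> StateModel:
    """Best-of-replicates k-means with Manhattan distance and median centroids."""
    if isinstance(x, FNCVectorSet):
        x = x.vectors
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(x) < k:
        raise ValueError("need at least k points")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    best: StateModel | None = None
    for _ in range(n_replicates):
        init = _distinct_init(x, k, rng)
        _, centroids, cost, trace = _lloyd_l1(x, init, max_iter)
        if best is None or cost < best.cost:
            best = StateModel(centroids=centroids, k=k, cost=cost, cost_trace=trace)
    assert best is not None
    return best


def assign_windows(
    model: StateModel,
    x: np.ndarray | FNCVectorSet,
    refine: bool = True,
    max_iter: int = 100,
) -> tuple[StateModel, np.ndarray]:
    """Assign every window to its nearest state (1-based labels).

    With ``refine=True`` (default) the exemplar-fit centroids seed one
    full k-means pass over all windows (centroids update to convergence)
    before the final nearest-centroid labeling; ``refine=False`` freezes
    the centroids.  L1 ties resolve to the lower state index.
    """
    if isinstance(x, FNCVectorSet):
        x = x.vectors
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError("edge dimension mismatch between data and centroids")
    if refine:
        _, centroids, cost, trace = _lloyd_l1(x, model.centroids, max_iter)
        model = StateModel(centroids=centroids, k=model.k, cost=cost, cost_trace=trace)
    labels, _ = _l1_cost(x, model.centroids)  # argmin ties -> lower index
    return model, labels + 1


def labels_to_sequences(labels: np.ndarray, provenance: pd.DataFrame) -> list[StateSequence]:
    """Split pooled window labels back into per-run state sequences."""
    df = provenance.copy()
    df["label"] = np.asarray(labels, dtype=int)
    out = []
    for (subject, condition), grp in df.groupby(["subject", "condition"], sort=False):
        grp = grp.sort_values("window")
        out.append(
            StateSequence(labels=grp["label"].to_numpy(), subject_id=subject, condition=condition)
        )
    return out


def validity_index(x: np.ndarray, model: StateModel, between: str = "point") -> float:
    """Ratio of within-cluster to between-cluster L1 distance.

    The numerator is the mean distance of each point to its own centroid.
    The denominator is, with ``between="point"`` (default), each point's
    mean distance to the other centroids — a stable between-cluster scale;
    with ``between="centroid"`` it is the mean pairwise centroid distance.
    """
    d = cdist(x, model.centroids, metric="cityblock")
    labels = d.argmin(axis=1)
    own = d[np.arange(len(x)), labels]
    within = float(own.mean())
    if between == "point":
        if model.k < 2:
            return np.inf
        sep = float(((d.sum(axis=1) - own) / (model.k - 1)).mean())
    elif between == "centroid":
        cd = cdist(model.centroids, model.centroids, metric="cityblock")
        iu = np.triu_indices(model.k, k=1)
        sep = float(cd[iu].mean())
    else:
        raise ValueError(f"unknown between mode: {between}")
    if sep == 0:
        return np.inf
    return within / sep


def _choose_elbow(k_range: list[int], index: np.ndarray) -> int:
    """Interior k with maximum perpendicular distance to the endpoint chord.

    The distance is signed: only candidates on the convex (below-chord)
    side qualify as an elbow of a decreasing index curve; points bulging
    above the chord are not bends toward diminishing returns.  Ties
    (including an exactly linear index, where every distance is zero)
    resolve to the smallest candidate k.
    """
    ks = np.asarray(k_range, dtype=float)
    p0 = np.array([ks[0], index[0]])
    p1 = np.array([ks[-1], index[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    # Positive when the point lies below the chord.
    dist = (chord[1] * (ks - p0[0]) - chord[0] * (index - p0[1])) / max(norm, 1e-300)
    scale = max(np.abs(index).max(), 1e-300)
    dist[np.abs(dist) < 1e-9 * scale] = 0.0  # collinear points are exact ties
    interior = slice(1, len(k_range) - 1)
    return k_range[1 + int(np.argmax(dist[interior]))]  # argmax ties -> smallest k


def elbow_select_k(
    x: np.ndarray | FNCVectorSet,
    k_range: list[int],
    seed: int | None = None,
    n_replicates: int = 10,
    max_iter: int = 100,
    between: str = "point",
) -> ClusterQuality:
    """Pick k at the elbow of the validity-index curve.

    The elbow is the interior candidate with the maximum perpendicular
    distance to the chord joining the curve's endpoints; ties resolve to
    the smallest k.
    """
    k_range = sorted(int(k) for k in k_range)
    if len(k_range) < 3:
        raise ValueError("k_range must contain at least 3 candidates (elbow undefined)")
    if k_range[0] < 2:
        raise ValueError("candidate k must be >= 2")
    if isinstance(x, FNCVectorSet):
        x = x.vectors
    rng = np.random.default_rng(seed)
    models: dict[int, StateModel] = {}
    index = np.empty(len(k_range))
    for i, k in enumerate(k_range):
        models[k] = kmeans_manhattan(x, k, n_replicates=n_replicates, max_iter=max_iter, seed=rng)
        index[i] = validity_index(x, models[k], between=between)
    chosen = _choose_elbow(k_range, index)
    return ClusterQuality(
        k_candidates=list(k_range), validity_index=index, chosen_k=chosen, models=models
    )
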