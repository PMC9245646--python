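"""Global/Local SO classification and SO-spindle coupling flags.

Every detected SO gets a binary co-occurrence footprint over the 22
channels: component j is 1 iff some SO trough on channel j lies within
±400 ms of the event's own trough. Footprints are clustered into K = 2
groups by a K-means procedure under Hamming distance (K-modes: binary
majority centroids, 200 random restarts, minimal total within-cluster
distance); the cluster with the larger mean footprint size is labelled
Global, the other Local. An SO is spindle-coupled when any spindle
interval on any channel intersects ±1 s of its trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import SOEvent

FOOTPRINT_TOLERANCE_S = 0.4
COUPLING_WINDOW_S = 1.0
DEFAULT_RESTARTS = 200


@dataclass
class Footprint:
    so_index: int
    vector: np.ndarray  # (n_channels,) of {0, 1}


@dataclass
class ClusterModel:
    centroids: np.ndarray       # (2, n_channels) binary
    labels: np.ndarray          # (n_events,) in {1, 2}
    cost: int                   # total within-cluster Hamming distance
    global_cluster: int         # 1 or 2

    def cluster_names(self) -> np.ndarray:
        """Map numeric labels onto {"Global", "Local"}."""
        return np.where(self.labels == self.global_cluster, "Global", "Local")


def build_footprints(events: list[SOEvent], channel_labels: list[str],
                     tolerance_s: float = FOOTPRINT_TOLERANCE_S) -> list[Footprint]:
    """Binary co-occurrence vectors, one per detected SO, over all channels."""
    n_ch = len(channel_labels)
    ch_index = {c: i for i, c in enumerate(channel_labels)}
    troughs = np.array([e.trough_time for e in events])
    chans = np.array([ch_index[e.channel] for e in events])
    footprints = []
    for i, ev in enumerate(events):
        v = np.zeros(n_ch, dtype=np.int8)
        near = np.abs(troughs - ev.trough_time) <= tolerance_s
        v[chans[near]] = 1
        v[ch_index[ev.channel]] = 1
        footprints.append(Footprint(so_index=i, vector=v))
    return footprints


def _assign(x: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, int]:
    # Hamming distances to both centroids; ties go to the lower cluster index
    d = np.array([np.sum(x != c, axis=1) for c in centroids])
    labels = np.argmin(d, axis=0)
    return labels, int(d[labels, np.arange(x.shape[0])].sum())


def _majority(x: np.ndarray) -> np.ndarray:
    # componentwise majority; exact ties resolve to 1 (inclusion)
    return (x.sum(axis=0) * 2 >= x.shape[0]).astype(np.int8)


def kmeans_hamming(footprints: list[Footprint], k: int = 2,
                   reps: int = DEFAULT_RESTARTS, seed: int = 0) -> ClusterModel:
    """K-modes clustering of binary footprints (K = 2).

    Each restart draws K distinct vectors as initial centroids, alternates
    minimum-Hamming assignment with majority-centroid updates until the
    cost stops decreasing, and the best of ``reps`` restarts is returned.
    Deterministic given the seed.
    """
    if k != 2:
        raise ValueError("the analysis clusters into exactly two groups")
    x = np.vstack([f.vector for f in footprints]).astype(np.int8)
    uniq = np.unique(x, axis=0)
    if uniq.shape[0] < k:
        raise ValueError("all footprints identical; clustering undefined")
    rng = np.random.default_rng(seed)
    best: tuple[int, np.ndarray, np.ndarray] | None = None
    for _ in range(reps):
        idx = rng.choice(uniq.shape[0], size=k, replace=False)
        centroids = uniq[idx].copy()
        labels, cost = _assign(x, centroids)
        for _ in range(100):
            new_centroids = centroids.copy()
            for c in range(k):
                members = x[labels == c]
                if members.size:
                    new_centroids[c] = _majority(members)
            new_labels, new_cost = _assign(x, new_centroids)
            if new_cost >= cost:
                break
            centroids, labels, cost = new_centroids, new_labels, new_cost
        if best is None or cost < best[0]:
            best = (cost, centroids.copy(), labels.copy())
    cost, centroids, labels0 = best
    sizes = [x[labels0 == c].sum(axis=1).mean() if np.any(labels0 == c) else -1.0
             for c in range(k)]
    global_cluster = int(np.argmax(sizes)) + 1
    return ClusterModel(centroids=centroids, labels=labels0 + 1, cost=cost,
                        global_cluster=global_cluster)


def brute_force_cost(vectors: np.ndarray) -> int:
    """Exhaustive minimum K=2 within-cluster Hamming cost (small n oracle)."""
    n = vectors.shape[0]
    best = None
    for mask in range(1, 2 ** (n - 1)):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0
        for group in (vectors[sel], vectors[~sel]):
            if group.shape[0] == 0:
                continue
            centroid = _majority(group)
            cost += int(np.sum(group != centroid))
        if best is None or cost < best:
            best = cost
    return best


def flag_coupling(so_events: list[SOEvent],
                  spindle_events: list[tuple[str, float, float]]) -> np.ndarray:
    """Per-SO coupling flag: any spindle interval intersecting trough ±1 s.

    Spindles are (channel, start_s, end_s); the spindle's channel is not
    restricted relative to the SO's. Returns a boolean array; the
    statistics stage encodes noncoupled = 1, coupled = 2.
    """
    for ch, start, end in spindle_events:
        if end < start:
            raise ValueError(f"malformed spindle interval on {ch}: {end} < {start}")
    flags = np.zeros(len(so_events), dtype=bool)
    for i, ev in enumerate(so_events):
        lo, hi = ev.trough_time - COUPLING_WINDOW_S, ev.trough_time + COUPLING_WINDOW_S
        flags[i] = any(start <= hi and end >= lo
                       for _, start, end in spindle_events)
    return flags
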