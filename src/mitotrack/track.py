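"""Time-reversed linking of detections into tracks and mitotic trajectories.

Tracking starts at the last frame and sequentially links objects to their
predecessors: the centroids of the current frame and of the (already
tracked) next frame are clustered jointly with Ward's linkage, the
dendrogram is cut at a distance cutoff, and within each cluster every
next-frame object links to its nearest current-frame object.  A
current-frame object that acquires exactly two successors with different
track ids marks a cell division at the successors' frame.  The cutoff is
either user-supplied or derived heuristically as half the average distance
of each object to its eight spatially nearest neighbours.

From the resulting track graph, mitotic trajectories are extracted for
divisions whose parent track is complete for ``n_before`` frames before the
division and both daughter tracks for ``n_after`` frames after it; the two
sister trajectories share the identical pre-division segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .detect import Detection

log = logging.getLogger(__name__)


@dataclass
class Division:
    frame: int          # first frame at which the two daughters exist
    parent: int
    daughter_a: int
    daughter_b: int


@dataclass
class TrackGraph:
    """Per-frame centroids with track ids plus annotated division events."""

    centroids: list[np.ndarray]       # per frame (n_t, 2) float, (y, x)
    track_ids: list[np.ndarray]       # per frame (n_t,) int
    divisions: list[Division] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.centroids)

    def track_table(self) -> dict[int, dict[int, int]]:
        """Mapping track_id -> {frame: index into that frame's arrays}."""
        table: dict[int, dict[int, int]] = {}
        for t, ids in enumerate(self.track_ids):
            for i, tid in enumerate(ids):
                table.setdefault(int(tid), {})[t] = i
        return table


@dataclass
class MitoticTrajectory:
    """One daughter branch with its shared pre-division history.

    ``frames`` covers ``[division_frame - n_before, division_frame +
    n_after)`` without gaps; ``centroids[i]`` is the (y, x) position at
    ``frames[i]`` (parent positions before the division, the daughter's own
    from the division frame on).
    """

    daughter: str               # "a" or "b"
    division_frame: int
    n_before: int
    n_after: int
    track_id: int
    parent_track: int
    frames: np.ndarray
    centroids: np.ndarray

    @property
    def window_length(self) -> int:
        return self.n_before + self.n_after

    @property
    def division_index(self) -> int:
        """Index of the division frame within the trajectory window."""
        return self.n_before


@dataclass
class SisterPair:
    a: MitoticTrajectory
    b: MitoticTrajectory

    @property
    def division_frame(self) -> int:
        return self.a.division_frame

    def sister_distance_px(self) -> np.ndarray:
        """Per-frame centroid distance in pixels; 0 before the division."""
        d = np.linalg.norm(self.a.centroids - self.b.centroids, axis=1)
        d[: self.a.n_before] = 0.0
        return d


def heuristic_cutoff(points: np.ndarray, n_neighbors: int = 8,
                     fallback: float | None = None) -> float:
    """Half the average distance of each object to its nearest neighbours.

    Uses ``min(n_neighbors, n - 1)`` neighbours for sparse frames.  A single
    detection falls back to ``fallback`` (error if not given); an empty
    input is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 and pts.size:
        pts = pts.reshape(-1, 2)
    n = len(pts)
    if n == 0:
        raise ValueError("heuristic_cutoff needs at least one detection")
    if n == 1:
        if fallback is None:
            raise ValueError(
                "heuristic_cutoff undefined for a single detection and no "
                "fallback cutoff was given")
        return float(fallback)
    k = min(n_neighbors, n - 1)
    d = cdist(pts, pts)
    d.sort(axis=1)
    return 0.5 * float(d[:, 1:k + 1].mean())


def link_backward(current_pts: np.ndarray, next_pts: np.ndarray,
                  cutoff: float) -> np.ndarray:
    """Link each next-frame object to a current-frame predecessor.

    Ward linkage is computed over the union of both point sets and cut at
    ``cutoff``; within each cluster every next-frame object links to the
    nearest current-frame object of that cluster.  Returns an int array of
    length ``len(next_pts)`` with the predecessor index or -1 (track birth
    in reversed time).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    cur = np.asarray(current_pts, float).reshape(-1, 2)
    nxt = np.asarray(next_pts, float).reshape(-1, 2)
    pred = np.full(len(nxt), -1, dtype=int)
    if len(cur) == 0 or len(nxt) == 0:
        return pred
    pts = np.vstack([cur, nxt])
    if len(pts) == 1:
        return pred
    if len(pts) == 2:
        labels = (np.ones(2, int) if np.linalg.norm(pts[0] - pts[1]) <= cutoff
                  else np.array([1, 2]))
    else:
        z = linkage(pts, method="ward")
        labels = fcluster(z, t=cutoff, criterion="distance")
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        cur_idx = members[members < len(cur)]
        nxt_idx = members[members >= len(cur)] - len(cur)
        if cur_idx.size == 0 or nxt_idx.size == 0:
            continue
        d = cdist(nxt[nxt_idx], cur[cur_idx])
        pred[nxt_idx] = cur_idx[np.argmin(d, axis=1)]
    return pred


def track_movie(detections: list[list[Detection]] | list[np.ndarray],
                cutoff: float | str = "auto",
                fallback_cutoff: float = 50.0) -> TrackGraph:
    """Assemble a :class:`TrackGraph` by backward linking of detections.

    ``cutoff`` is a pixel distance or ``"auto"`` (per-frame heuristic).
    Deterministic: ties in the Ward dendrogram are resolved by scipy's fixed
    node ordering and equal-distance predecessors by the lowest index.
    """
    cents = []
    for frame in detections:
        if len(frame) and isinstance(frame[0], Detection):
            cents.append(np.array([[d.y, d.x] for d in frame], float))
        else:
            cents.append(np.asarray(frame, float).reshape(-1, 2))
    t_total = len(cents)
    ids: list[np.ndarray] = [np.empty(len(c), dtype=int) for c in cents]
    divisions: list[Division] = []
    next_id = 0

    def fresh() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    if t_total == 0:
        return TrackGraph([], [])
    ids[-1] = np.array([fresh() for _ in range(len(cents[-1]))], dtype=int)

    for t in range(t_total - 2, -1, -1):
        cur, nxt = cents[t], cents[t + 1]
        if len(cur) == 0:
            ids[t] = np.empty(0, dtype=int)
            continue
        if len(nxt) == 0:
            ids[t] = np.array([fresh() for _ in range(len(cur))], dtype=int)
            continue
        c = (heuristic_cutoff(cur, fallback=fallback_cutoff)
             if cutoff == "auto" else float(cutoff))
        pred = link_backward(cur, nxt, c)
        successors: dict[int, list[int]] = {}
        for j, i in enumerate(pred):
            if i >= 0:
                successors.setdefault(int(i), []).append(j)
        ids_t = np.empty(len(cur), dtype=int)
        for i in range(len(cur)):
            succ = successors.get(i, [])
            if len(succ) == 1:
                ids_t[i] = ids[t + 1][succ[0]]
            elif len(succ) == 2:
                parent = fresh()
                ids_t[i] = parent
                da, db = (int(ids[t + 1][succ[0]]), int(ids[t + 1][succ[1]]))
                divisions.append(Division(frame=t + 1, parent=parent,
                                          daughter_a=da, daughter_b=db))
            elif len(succ) > 2:
                log.warning("frame %d: object %d has %d successors; "
                            "division rejected", t, i, len(succ))
                ids_t[i] = fresh()
            else:
                ids_t[i] = fresh()
        ids[t] = ids_t
    return TrackGraph(centroids=cents, track_ids=ids, divisions=divisions)


def extract_mitotic_trajectories(graph: TrackGraph, n_before: int = 30,
                                 n_after: int = 60) -> list[SisterPair]:
    """Extract complete sister-pair trajectories around each division.

    Only divisions whose parent track spans at least ``n_before`` frames
    before the division and whose daughters both span at least ``n_after``
    frames after it are returned; windows are trimmed to exactly
    ``[f - n_before, f + n_after)``.
    """
    table = graph.track_table()
    pairs: list[SisterPair] = []
    for div in graph.divisions:
        f = div.frame
        if f - n_before < 0 or f + n_after > graph.n_frames:
            continue
        pre_frames = range(f - n_before, f)
        post_frames = range(f, f + n_after)
        parent = table.get(div.parent, {})
        if not all(t in parent for t in pre_frames):
            continue
        branches = {}
        ok = True
        for name, tid in (("a", div.daughter_a), ("b", div.daughter_b)):
            tf = table.get(tid, {})
            if not all(t in tf for t in post_frames):
                ok = False
                break
            pre = np.array([graph.centroids[t][parent[t]] for t in pre_frames])
            post = np.array([graph.centroids[t][tf[t]] for t in post_frames])
            branches[name] = MitoticTrajectory(
                daughter=name, division_frame=f, n_before=n_before,
                n_after=n_after, track_id=tid, parent_track=div.parent,
                frames=np.arange(f - n_before, f + n_after),
                centroids=np.vstack([pre, post]))
        if ok:
            pairs.append(SisterPair(a=branches["a"], b=branches["b"]))
    return pairs
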