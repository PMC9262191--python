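"""Mitotic-state assignment and anchor detection for cell trajectories.

Each trajectory frame receives a state label: 0 invalid, 1 interphase,
2 prophase through early anaphase, 3 late anaphase/telophase.  Valid
trajectories are monotone block sequences 1...1 2...2 3...3; the IP anchor
is the first state-2 frame, the MA anchor the first state-3 frame, and both
sister trajectories always share identical states.

The classifier-free default pathway finds IP with a temporally constrained
two-cluster split (TC3) of the pre-division features (area, circularity,
mean intensity, intensity std., z-scored) and MA as the first post-division
frame at which the sister centroid distance exceeds a distance threshold.
Any per-frame state classifier can be plugged in through a (T, 4)
probability table decoded by a Viterbi pass over an HMM that only allows
the transitions 1->1, 1->2, 2->2, 2->3, 3->3 and 0->0.  Manual annotations
(two clicks: last interphase frame and early anaphase frame, or whole-track
rejection) are consumed from CSV files and copied to the sibling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: z-scored feature columns used by the classical IP detector
TC3_FEATURES = ("area", "circularity", "mean_int", "std_int")

#: default distance threshold for MA repositioning, px at 0.65 um/px
DEFAULT_MA_THRESHOLD_PX = 10.0

#: default HMM transition matrix over states (0, 1, 2, 3): staying
#: probability 0.9, allowed advance 0.1, illegal transitions 0
DEFAULT_TRANSITIONS = np.array([
    [1.0, 0.0, 0.0, 0.0],
    [0.0, 0.9, 0.1, 0.0],
    [0.0, 0.0, 0.9, 0.1],
    [0.0, 0.0, 0.0, 1.0],
])

#: start distribution permits only states 0 and 1
DEFAULT_START = np.array([0.5, 0.5, 0.0, 0.0])


def ma_threshold_for_pixel_size(pixel_size_um: float,
                                reference_pixel_size: float = 0.65) -> float:
    """Scale the default 10 px MA threshold to another resolution."""
    return DEFAULT_MA_THRESHOLD_PX * reference_pixel_size / pixel_size_um


@dataclass
class SyncStates:
    states: np.ndarray          # (T,) int8 labels in {0, 1, 2, 3}
    ip_index: int               # first state-2 frame, -1 if invalid
    ma_index: int               # first state-3 frame, -1 if invalid
    valid: bool
    low_confidence: bool = False

    @classmethod
    def from_anchors(cls, length: int, ip_index: int, ma_index: int,
                     low_confidence: bool = False) -> "SyncStates":
        if not (0 < ip_index < ma_index <= length):
            raise ValueError(
                f"need 0 < ip ({ip_index}) < ma ({ma_index}) <= {length}")
        states = np.empty(length, dtype=np.int8)
        states[:ip_index] = 1
        states[ip_index:ma_index] = 2
        states[ma_index:] = 3
        return cls(states=states, ip_index=ip_index, ma_index=ma_index,
                   valid=True, low_confidence=low_confidence)

    @classmethod
    def invalid(cls, length: int) -> "SyncStates":
        return cls(states=np.zeros(length, dtype=np.int8), ip_index=-1,
                   ma_index=-1, valid=False)

    def is_monotone_block(self) -> bool:
        s = self.states
        if not self.valid:
            return bool(np.all(s == 0))
        return bool(np.all(np.diff(s) >= 0) and s[0] >= 1
                    and set(np.unique(s)) <= {1, 2, 3})


# ---------------------------------------------------------------------------
# TC3 split and classical anchors
# ---------------------------------------------------------------------------

def zscore_columns(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def tc3_split(feature_matrix: np.ndarray,
              search_range: tuple[int, int] | None = None,
              zscore: bool = True) -> tuple[int, float]:
    """Best contiguous two-cluster split of a feature time series.

    Finds the split index s minimizing the total within-cluster sum of
    squares of ``x[start:s]`` and ``x[s:end]`` by exhaustive search over all
    contiguous splits - the constrained two-cluster optimum.  Ties are
    broken toward the earliest split.  Returns ``(s, cost)``; s satisfies
    ``start < s < end``.
    """
    x = np.asarray(feature_matrix, float)
    if x.ndim == 1:
        x = x[:, None]
    start, end = (0, len(x)) if search_range is None else search_range
    if end - start < 2:
        raise ValueError("tc3_split needs at least 2 frames in the range")
    window = x[start:end]
    window = np.where(np.isfinite(window), window,
                      np.nanmean(np.where(np.isfinite(window), window, np.nan),
                                 axis=0))
    if zscore:
        window = zscore_columns(window)
    n = len(window)
    best_s, best_cost = 1, math.inf
    for s in range(1, n):
        c1 = window[:s] - window[:s].mean(axis=0)
        c2 = window[s:] - window[s:].mean(axis=0)
        cost = float((c1 * c1).sum() + (c2 * c2).sum())
        if cost < best_cost:
            best_cost, best_s = cost, s
    return start + best_s, best_cost


def detect_ip(feature_matrix: np.ndarray,
              pre_division_frames: int,
              confidence_ratio: float = 1.2) -> tuple[int, bool]:
    """IP anchor by TC3 split of the pre-division feature block.

    ``feature_matrix`` is (T, 4) with columns (area, circularity, mean
    intensity, intensity std); only rows ``[0, pre_division_frames)`` are
    searched.  Returns ``(ip_index, low_confidence)``: the trajectory is
    flagged (not rejected) when the best split improves on a constant model
    by less than the confidence ratio - e.g. a trajectory that never
    condenses its chromatin.
    """
    if pre_division_frames < 2:
        raise ValueError("need at least 2 pre-division frames")
    ip, best_cost = tc3_split(feature_matrix, (0, pre_division_frames))
    window = zscore_columns(np.asarray(feature_matrix, float)[:pre_division_frames])
    centered = window - window.mean(axis=0)
    constant_cost = float((centered * centered).sum())
    low_confidence = best_cost > 0 and constant_cost / best_cost < confidence_ratio
    return ip, low_confidence


def reposition_ma(sister_distance_px: np.ndarray, division_index: int,
                  threshold_px: float = DEFAULT_MA_THRESHOLD_PX) -> int:
    """First post-division frame with sister distance above the threshold.

    Falls back to the division frame itself when the threshold is never
    exceeded (no repositioning).
    """
    d = np.asarray(sister_distance_px, float)
    for t in range(division_index, len(d)):
        if d[t] > threshold_px:
            return t
    return division_index


def classical_sync(feature_matrix: np.ndarray,
                   sister_distance_px: np.ndarray,
                   division_index: int,
                   ma_threshold_px: float = DEFAULT_MA_THRESHOLD_PX,
                   confidence_ratio: float = 1.2) -> SyncStates:
    """Classifier-free synchronization: TC3 IP + distance-threshold MA."""
    ip, low_conf = detect_ip(feature_matrix, division_index,
                             confidence_ratio=confidence_ratio)
    ma = reposition_ma(sister_distance_px, division_index, ma_threshold_px)
    length = len(np.asarray(feature_matrix))
    if not (0 < ip < ma <= length):
        return SyncStates.invalid(length)
    out = SyncStates.from_anchors(length, ip, ma, low_confidence=low_conf)
    return out


# ---------------------------------------------------------------------------
# HMM pathway
# ---------------------------------------------------------------------------

def state_probabilities(feature_matrix: np.ndarray,
                        sister_distance_px: np.ndarray,
                        ma_threshold_px: float = DEFAULT_MA_THRESHOLD_PX,
                        invalid_floor: float = 0.02) -> np.ndarray:
    """Built-in feature-based per-frame state probability model.

    A fixed-coefficient logistic (softmax) model on the z-scored classical
    features plus the normalized sister separation; it stands in for any
    external per-frame classifier and feeds :func:`viterbi_decode`.  Rows
    sum to 1; state 0 keeps a small constant floor so the all-invalid path
    stays available to the decoder.
    """
    x = zscore_columns(feature_matrix)
    area_z, mean_z = x[:, 0], x[:, 2]
    d = np.asarray(sister_distance_px, float) / ma_threshold_px
    s1 = area_z - mean_z - 8.0 * np.clip(d - 0.6, 0.0, None)
    s2 = mean_z - area_z - 8.0 * np.clip(d - 0.6, 0.0, None)
    s3 = 8.0 * (d - 0.6)
    scores = np.stack([s1, s2, s3], axis=1)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    soft = e / e.sum(axis=1, keepdims=True)
    probs = np.empty((len(x), 4))
    probs[:, 0] = invalid_floor
    probs[:, 1:] = (1.0 - invalid_floor) * soft
    return probs


def viterbi_path(probs: np.ndarray,
                 transitions: np.ndarray = DEFAULT_TRANSITIONS,
                 start: np.ndarray = DEFAULT_START) -> np.ndarray:
    """Most likely state path (raw, before validity interpretation).

    ``probs`` is (T, 4) over states (0, 1, 2, 3); each row must contain at
    least one positive entry.  Decoding is in log space; ties prefer the
    lower state index.
    """
    p = np.asarray(probs, float)
    if p.ndim != 2 or p.shape[1] != 4:
        raise ValueError("probs must be (T, 4)")
    if np.any(p.sum(axis=1) <= 0):
        raise ValueError("degenerate classifier: a frame has all-zero "
                         "state probabilities")
    t_len = len(p)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log_a = np.log(np.asarray(transitions, float))
        log_s = np.log(np.asarray(start, float))
    delta = log_s + logp[0]
    back = np.zeros((t_len, 4), dtype=np.int8)
    for t in range(1, t_len):
        scores = delta[:, None] + log_a          # scores[i, j]: i -> j
        back[t] = np.argmax(scores, axis=0)      # lowest index wins ties
        delta = scores[back[t], np.arange(4)] + logp[t]
    path = np.empty(t_len, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_decode(probs: np.ndarray,
                   transitions: np.ndarray = DEFAULT_TRANSITIONS,
                   start: np.ndarray = DEFAULT_START) -> SyncStates:
    """Decode per-frame state probabilities into :class:`SyncStates`.

    If the winning path is the all-0 path the trajectory is invalid; a path
    that never reaches states 2 and 3 is also marked invalid (no complete
    mitotic event).  Otherwise the anchors derive from the state changes.
    """
    path = viterbi_path(probs, transitions, start)
    t_len = len(path)
    if np.all(path == 0):
        return SyncStates.invalid(t_len)
    if 2 not in path or 3 not in path:
        return SyncStates.invalid(t_len)
    ip = int(np.argmax(path == 2))
    ma = int(np.argmax(path == 3))
    return SyncStates.from_anchors(t_len, ip, ma)


# ---------------------------------------------------------------------------
# manual annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("cell_id", "last_interphase_frame",
                      "early_anaphase_frame", "reject")


def load_annotations(path) -> pd.DataFrame:
    """Read a manual-annotation CSV (cell_id, last_interphase_frame,
    early_anaphase_frame, reject)."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    return df


def apply_annotation(length: int, last_interphase_frame: int,
                     early_anaphase_frame: int,
                     reject: bool = False) -> tuple[SyncStates, SyncStates]:
    """Turn a two-click annotation into sibling-shared states.

    The IP anchor is the frame after the last interphase frame and the MA
    anchor the frame after the early anaphase frame; all intermediate
    frames are classified accordingly and the annotation is copied
    bit-identically to the sibling.  Rejection marks the whole track (and
    its sibling) invalid.
    """
    if reject:
        s = SyncStates.invalid(length)
        return s, SyncStates.invalid(length)
    ip = int(last_interphase_frame) + 1
    ma = int(early_anaphase_frame) + 1
    if ma <= ip:
        raise ValueError(
            f"rejected annotation: early anaphase frame {early_anaphase_frame}"
            f" not after last interphase frame {last_interphase_frame}")
    a = SyncStates.from_anchors(length, ip, ma)
    b = SyncStates(states=a.states.copy(), ip_index=a.ip_index,
                   ma_index=a.ma_index, valid=a.valid)
    return a, b
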