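"""Event-anchored transforms of raw feature time series.

Absolute feature values differ between microscopes and acquisition
settings; normalizing each cell's series to a cell-cycle event - the
average interphase value or the value at the first late-anaphase frame -
makes time series comparable across experiments.  The module also provides
series smoothing, windowed regression slopes (e.g. the initial recovery
rate right after division) and the interphase-recovery feature, where 100%
indicates full recovery of the selected features to their interphase means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sync import SyncStates

#: default feature set of the combined recovery readout
RECOVERY_FEATURES = ("area", "minor_axis", "mean_int", "std_int")

SMOOTH_METHODS = ("moving_average", "lowess", "savitzky_golay")


def smooth_series(series: np.ndarray, window: int,
                  method: str = "moving_average") -> np.ndarray:
    """Smooth a series, keeping its length.

    ``window`` must be odd and no longer than the series.  At the edges the
    moving-average window shrinks to the available samples.  ``lowess`` and
    ``savitzky_golay`` delegate to statsmodels and scipy respectively.
    """
    x = np.asarray(series, float)
    n = len(x)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if method not in SMOOTH_METHODS:
        raise ValueError(f"unknown method '{method}'; use one of {SMOOTH_METHODS}")
    if window == 1:
        return x.copy()
    if method == "moving_average":
        half = window // 2
        out = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[i] = x[lo:hi].mean()
        return out
    if method == "savitzky_golay":
        from scipy.signal import savgol_filter
        return savgol_filter(x, window_length=window,
                             polyorder=min(2, window - 1), mode="interp")
    from statsmodels.nonparametric.smoothers_lowess import lowess
    return lowess(x, np.arange(n), frac=window / n, return_sorted=False)


def normalize_to_event(series: np.ndarray, sync: SyncStates,
                       mode: str = "interphase_mean") -> np.ndarray:
    """Divide a series by an event-anchored reference value.

    ``interphase_mean`` divides by the mean over state-1 frames;
    ``first_late_anaphase`` by the value at the MA anchor (which becomes
    exactly 1).  A zero or undefined reference yields an all-NaN series
    (flagged missing, never zero-filled).
    """
    x = np.asarray(series, float)
    if not sync.valid:
        return np.full_like(x, np.nan)
    if mode == "interphase_mean":
        ref_vals = x[sync.states == 1]
        denom = float(ref_vals.mean()) if ref_vals.size else float("nan")
    elif mode == "first_late_anaphase":
        denom = float(x[sync.ma_index])
    else:
        raise ValueError(f"unknown normalization mode '{mode}'")
    if not np.isfinite(denom) or denom == 0:
        return np.full_like(x, np.nan)
    return x / denom


def regression_slope(series: np.ndarray, anchor_index: int, window: int = 5,
                     sampling_interval: float | None = None) -> float:
    """OLS slope of the series over ``[anchor, anchor + window)``.

    The slope is per frame; pass ``sampling_interval`` (minutes/frame) to
    obtain it per minute instead.  Missing values inside the window are
    dropped; fewer than 2 remaining points yield NaN.
    """
    if window < 2:
        raise ValueError("regression window must span at least 2 frames")
    x = np.asarray(series, float)[anchor_index:anchor_index + window]
    t = np.arange(len(x), dtype=float)
    good = np.isfinite(x)
    if good.sum() < 2:
        return float("nan")
    slope = np.polyfit(t[good], x[good], 1)[0]
    if sampling_interval is not None:
        slope /= sampling_interval
    return float(slope)


def recovery_percentage(features: dict[str, np.ndarray], sync: SyncStates,
                        selected=RECOVERY_FEATURES,
                        clip_deviation: bool = True) -> np.ndarray:
    """Interphase-recovery time series in percent.

    For each post-mitotic (state-3) frame the absolute percentage deviation
    of every selected feature from its own interphase mean is averaged and
    subtracted from 100, so 100% indicates full recovery (every selected
    feature back at its interphase mean).  Deviations above 100% are
    clipped, keeping the result in [0, 100].  Features with a zero
    interphase mean are dropped from the average with a warning.  Frames
    outside state 3 are NaN.
    """
    if not sync.valid:
        length = len(next(iter(features.values())))
        return np.full(length, np.nan)
    length = len(sync.states)
    post = sync.states == 3
    interphase = sync.states == 1
    deviations = []
    for name in selected:
        if name not in features:
            raise KeyError(f"feature '{name}' not available for recovery")
        x = np.asarray(features[name], float)
        ref = x[interphase]
        mu = float(np.nanmean(ref)) if ref.size else float("nan")
        if not np.isfinite(mu) or mu == 0:
            warnings.warn(f"recovery: feature '{name}' has zero/undefined "
                          "interphase mean and is dropped", stacklevel=2)
            continue
        dev = np.abs(x - mu) / abs(mu) * 100.0
        if clip_deviation:
            dev = np.minimum(dev, 100.0)
        deviations.append(dev)
    out = np.full(length, np.nan)
    if not deviations:
        return out
    mean_dev = np.nanmean(np.stack(deviations), axis=0)
    out[post] = 100.0 - mean_dev[post]
    return out
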