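"""Nucleus centroid detection via multi-scale Laplacian-of-Gaussian filtering.

The detector computes the scale-normalized negated LoG response
``-sigma^2 * LoG(I, sigma)`` over a set of scales, finds local maxima of the
(scale, y, x) response volume above a threshold relative to the per-frame
maximum response, merges maxima closer than ``sigma * sqrt(2)`` keeping the
stronger one, and refines each centroid by the intensity-weighted centroid
of its 3x3 response neighbourhood.  The relative threshold makes detections
invariant to global intensity scaling across microscopes, and the LoG
removes any constant intensity offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass
class Detection:
    frame: int
    y: float
    x: float
    scale: float
    response: float


def make_resolution_preset(pixel_size_um: float,
                           expected_diameter_um: float = 13.0
                           ) -> tuple[tuple[float, float], float]:
    """Derive an LoG scale range for a given resolution.

    A blob of radius r responds maximally at ``sigma = r / sqrt(2)``, so the
    scale range is centred at ``diameter / (2 sqrt(2) pixel_size)`` and spans
    +-40%.  Returns ``(sigma_range, threshold_rel)``.
    """
    if pixel_size_um <= 0 or expected_diameter_um <= 0:
        raise ValueError("pixel size and expected diameter must be > 0")
    center = expected_diameter_um / (2.0 * math.sqrt(2.0) * pixel_size_um)
    return (0.6 * center, 1.4 * center), 0.1


def detect_nuclei(frame_image: np.ndarray,
                  sigma_range: tuple[float, float] = (3.5, 8.0),
                  threshold_rel: float = 0.1,
                  n_scales: int = 6,
                  frame: int = 0) -> list[Detection]:
    """Detect bright blobs in one grayscale frame.

    Returns an empty list for blank images.  Deterministic; detections are
    sorted by descending filter response.
    """
    smin, smax = sigma_range
    if not (0 < smin <= smax):
        raise ValueError("need 0 < sigma_min <= sigma_max")
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a single 2D frame")
    # remove the DC component: the truncated discrete LoG kernel does not
    # sum exactly to zero, so a constant offset would leak into the response
    img = img - float(img.mean())
    sigmas = np.linspace(smin, smax, n_scales) if smax > smin else np.array([smin])
    resp = np.stack([-(s * s) * ndi.gaussian_laplace(img, s) for s in sigmas])
    rmax = float(resp.max(initial=0.0))
    if rmax <= 0:
        return []
    thr = threshold_rel * rmax
    local_max = ndi.maximum_filter(resp, size=3, mode="nearest")
    cand = np.argwhere((resp >= local_max) & (resp > thr))
    if cand.size == 0:
        return []
    strengths = resp[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(-strengths, kind="stable")

    kept: list[Detection] = []
    for idx in order:
        s_i, y_i, x_i = cand[idx]
        sigma = float(sigmas[s_i])
        merged = False
        for det in kept:
            merge_dist = max(det.scale, sigma) * math.sqrt(2)
            if math.hypot(det.y - y_i, det.x - x_i) < merge_dist:
                merged = True
                break
        if merged:
            continue
        yy, xx = _refine_subpixel(resp[s_i], int(y_i), int(x_i))
        kept.append(Detection(frame=frame, y=yy, x=xx, scale=sigma,
                              response=float(strengths[idx])))
    return kept


def _refine_subpixel(plane: np.ndarray, y: int, x: int) -> tuple[float, float]:
    h, w = plane.shape
    y0, y1 = max(0, y - 1), min(h, y + 2)
    x0, x1 = max(0, x - 1), min(w, x + 2)
    win = np.clip(plane[y0:y1, x0:x1], 0, None)
    total = win.sum()
    if total <= 0:
        return float(y), float(x)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((win * yy).sum() / total), float((win * xx).sum() / total)


def detect_movie(frames: np.ndarray,
                 sigma_range: tuple[float, float] = (3.5, 8.0),
                 threshold_rel: float = 0.1,
                 n_scales: int = 6) -> list[list[Detection]]:
    """Run :func:`detect_nuclei` on every frame of a ``(T, H, W)`` stack."""
    return [detect_nuclei(frames[t], sigma_range, threshold_rel, n_scales, frame=t)
            for t in range(frames.shape[0])]
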