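"""Central-cell segmentation of patches around tracked detections.

The classical pipeline median-filters the patch (5x5), binarizes it at the
arithmetic mean of a 256-bin Otsu threshold and the minimum filtered
intensity in the central part of the patch (which protects a dim central
cell surrounded by brighter neighbours from being thresholded away), and
separates the central cell from its neighbours with a two-seed watershed -
one seed at the patch centre, one covering the patch border - on the
inverted Euclidean distance map of the binarization.

Externally produced instance segmentations (16-bit label images, 0 =
background) can be merged instead: the label found at, or nearest to, the
patch centre is kept and the classical pipeline serves as fallback where no
label is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class CellPatch:
    """A square crop with its central-cell mask and crop origin."""

    image: np.ndarray            # (S, S) intensity patch, chromatin channel
    mask: np.ndarray             # (S, S) bool, single 4-connected component
    origin: tuple[int, int]      # (y, x) of patch corner in frame coordinates
    ok: bool                     # False when segmentation failed (empty mask)
    fallback: bool = False       # classical fallback used instead of labels


def default_patch_size(pixel_size_um: float, reference_px: int = 96,
                       reference_pixel_size: float = 0.65) -> int:
    """Patch side in pixels, scaled to cover a constant physical field.

    96 px at 0.65 um/px fits one HeLa nucleus plus margin; the side scales
    inversely with pixel size and is rounded to an even number.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    size = reference_px * reference_pixel_size / pixel_size_um
    return max(16, int(round(size / 2.0)) * 2)


def crop_patch(image: np.ndarray, center: tuple[float, float],
               size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop a ``size`` x ``size`` patch centred on ``center`` (y, x).

    Regions outside the frame are padded with the frame minimum so border
    crops stay square.  Returns the patch and its (y, x) origin.
    """
    h, w = image.shape
    cy, cx = int(round(center[0])), int(round(center[1]))
    half = size // 2
    y0, x0 = cy - half, cx - half
    y1, x1 = y0 + size, x0 + size
    ys0, xs0 = max(0, y0), max(0, x0)
    ys1, xs1 = min(h, y1), min(w, x1)
    patch = np.full((size, size), image.min(), dtype=image.dtype)
    patch[ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = image[ys0:ys1, xs0:xs1]
    return patch, (y0, x0)


def otsu_threshold(image_patch: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    Bins span the patch's min-max range, making the threshold independent of
    dtype and equivariant under intensity shifts (up to one bin width).
    Constant patches are rejected.
    """
    vals = np.asarray(image_patch, dtype=float).ravel()
    mn, mx = float(vals.min()), float(vals.max())
    if mx == mn:
        raise ValueError("constant patch: Otsu threshold undefined")
    hist, edges = np.histogram(vals, bins=nbins, range=(mn, mx))
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(p)                  # weight of class 1 = bins [0, k]
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between = between[:-1]                # boundary after bin k, k < nbins-1
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between))
    return float(edges[k + 1])


def segment_patch_classical(patch: np.ndarray, center_fraction: float = 0.5
                            ) -> tuple[np.ndarray, bool]:
    """Classical central-cell segmentation of one patch.

    Pipeline: 5x5 median filter; threshold ``(otsu + min_center) / 2`` where
    ``min_center`` is the filtered minimum inside the central square
    covering ``center_fraction`` of the patch side; two-seed watershed on
    the inverted Euclidean distance map - seed 1 at the patch centre, seed
    2 for the background and the neighbouring cells (the border ring plus
    off-centre distance-map maxima, i.e. the intensity minima of the
    inverted map located in the centres of the other nuclei); the
    centre-seed region intersected with the binarization, reduced to the
    4-connected component at the patch centre with holes filled.  Returns
    ``(mask, ok)``; a degenerate binarization yields an empty mask with
    ``ok=False``.
    """
    patch = np.asarray(patch, dtype=float)
    s = patch.shape[0]
    if patch.shape[0] != patch.shape[1] or s < 8:
        raise ValueError("expected a square patch of side >= 8")
    med = ndi.median_filter(patch, size=5)
    try:
        t_otsu = otsu_threshold(med)
    except ValueError:
        return np.zeros_like(patch, bool), False
    half = max(1, int(round(center_fraction * s / 2.0)))
    c = s // 2
    min_center = float(med[c - half:c + half, c - half:c + half].min())
    threshold = 0.5 * (t_otsu + min_center)
    binary = med >= threshold
    if not binary.any():
        return np.zeros_like(binary), False
    edt = ndi.distance_transform_edt(binary)
    markers = np.zeros(patch.shape, dtype=np.int32)
    markers[0, :] = markers[-1, :] = markers[:, 0] = markers[:, -1] = 2
    for py, px in _neighbor_seeds(edt, (c, c), min_dist=max(6, s // 10)):
        markers[py, px] = 2
    markers[c, c] = 1
    regions = watershed(-edt, markers)
    mask = (regions == 1) & binary
    mask = _central_component(mask, (c, c))
    if not mask.any():
        return mask, False
    return ndi.binary_fill_holes(mask, structure=FOUR_CONNECTED), True


def _neighbor_seeds(edt: np.ndarray, center: tuple[int, int],
                    min_dist: float) -> np.ndarray:
    """Distance-map maxima away from the patch centre (neighbouring nuclei)."""
    from skimage.feature import peak_local_max

    peaks = peak_local_max(edt, min_distance=3, exclude_border=False)
    if peaks.size == 0:
        return peaks.reshape(0, 2)
    d = np.hypot(peaks[:, 0] - center[0], peaks[:, 1] - center[1])
    return peaks[d > min_dist]


def _central_component(mask: np.ndarray, center: tuple[int, int],
                       search_radius: float = 5.0) -> np.ndarray:
    """Keep the 4-connected component at (or nearest within r of) center."""
    labeled, n = ndi.label(mask, structure=FOUR_CONNECTED)
    if n == 0:
        return np.zeros_like(mask)
    cy, cx = center
    lab = labeled[cy, cx]
    if lab == 0:
        fg = np.argwhere(labeled > 0)
        d = np.hypot(fg[:, 0] - cy, fg[:, 1] - cx)
        i = int(np.argmin(d))
        if d[i] > search_radius:
            return np.zeros_like(mask)
        lab = labeled[fg[i, 0], fg[i, 1]]
    return labeled == lab


def merge_instance_segmentation(label_image: np.ndarray,
                                centers: list[tuple[float, float]],
                                patch_size: int,
                                intensity_image: np.ndarray | None = None,
                                search_radius: float = 5.0,
                                center_fraction: float = 0.5
                                ) -> list[CellPatch]:
    """Derive central-cell masks from an external instance segmentation.

    For each detection centre the label image is cropped with the same
    patch geometry as the classical pipeline and only the instance found at
    (or nearest to, within ``search_radius`` px of) the patch centre is
    kept.  Where no instance is present the classical segmentation of the
    intensity patch is substituted and flagged as fallback.
    """
    if intensity_image is not None and label_image.shape != intensity_image.shape:
        raise ValueError("label image dimensions must equal frame dimensions")
    out: list[CellPatch] = []
    c = patch_size // 2
    for center in centers:
        lab_patch, origin = crop_patch(label_image, center, patch_size)
        img_patch = (crop_patch(intensity_image, center, patch_size)[0]
                     if intensity_image is not None
                     else np.zeros_like(lab_patch, float))
        lab = lab_patch[c, c]
        if lab == 0:
            fg = np.argwhere(lab_patch > 0)
            if fg.size:
                d = np.hypot(fg[:, 0] - c, fg[:, 1] - c)
                i = int(np.argmin(d))
                if d[i] <= search_radius:
                    lab = lab_patch[fg[i, 0], fg[i, 1]]
        if lab != 0:
            mask = lab_patch == lab
            out.append(CellPatch(image=np.asarray(img_patch, float), mask=mask,
                                 origin=origin, ok=True, fallback=False))
        else:
            if intensity_image is not None:
                mask, ok = segment_patch_classical(img_patch, center_fraction)
            else:
                mask, ok = np.zeros_like(lab_patch, bool), False
            out.append(CellPatch(image=np.asarray(img_patch, float), mask=mask,
                                 origin=origin, ok=ok, fallback=True))
    return out


def segment_detection(image: np.ndarray, center: tuple[float, float],
                      patch_size: int, center_fraction: float = 0.5,
                      label_image: np.ndarray | None = None,
                      search_radius: float = 5.0) -> CellPatch:
    """Segment one tracked detection, preferring external labels if given."""
    if label_image is not None:
        return merge_instance_segmentation(
            label_image, [center], patch_size, intensity_image=image,
            search_radius=search_radius, center_fraction=center_fraction)[0]
    patch, origin = crop_patch(image, center, patch_size)
    mask, ok = segment_patch_classical(patch, center_fraction)
    return CellPatch(image=np.asarray(patch, float), mask=mask, origin=origin,
                     ok=ok, fallback=False)
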