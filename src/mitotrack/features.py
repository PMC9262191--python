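"""Per-frame cell features: morphology, intensity, texture and geometry.

Morphological features come from the mask's second central moments (ellipse
with equal moments); circularity uses the 8-connected boundary contour
length so a rasterized disk stays close to 1.  Orientation is axial
(nuclei have no head or tail): degrees from the +x (column) axis, wrapped
into [-90, 90).

Haralick texture statistics are computed from gray level co-occurrence
matrices with 64 levels quantized over the patch's min-max range (making
texture invariant to linear intensity scaling across platforms), with
background-to-foreground transitions removed - only pixel pairs where both
pixels lie inside the mask are counted - for the four neighbour relations
(0,1), (1,0), (1,1), (-1,1), averaged across the relations.  The 13 primary
statistics are implemented; the numerically unstable 14th (maximal
correlation coefficient) is omitted.  Logarithms are base 2, so entropies
are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours
from skimage.morphology import disk

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (-1, 1))


def boundary_contour_length(mask: np.ndarray, smoothing: float = 0.8) -> float:
    """Length of the traced boundary contour(s) of a binary region.

    The region is padded so border-touching masks close, lightly smoothed
    to suppress the staircase bias of a raw pixel contour, traced at the
    half-level and the polyline lengths summed; a rasterized disk of radius
    r yields ~2*pi*r, keeping circularity near 1.
    """
    padded = np.pad(np.asarray(mask, float), 2)
    if smoothing > 0:
        padded = ndi.gaussian_filter(padded, smoothing)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        total += float(np.sum(np.linalg.norm(np.diff(contour, axis=0),
                                             axis=1)))
    return total


def wrap_axial(deg):
    """Wrap an axial (mod-180) angle difference into [-90, 90)."""
    return (np.asarray(deg, float) + 90.0) % 180.0 - 90.0


# ---------------------------------------------------------------------------
# classical region features
# ---------------------------------------------------------------------------

@dataclass
class RegionFeatures:
    area: float                # um^2
    area_px: float
    centroid: tuple[float, float]
    major_axis: float          # um
    minor_axis: float          # um
    orientation: float         # deg in [-90, 90)
    circularity: float
    mean_int: float
    std_int: float
    max_int: float
    min_int: float
    missing: bool = False

    @classmethod
    def empty(cls) -> "RegionFeatures":
        nan = float("nan")
        return cls(nan, nan, (nan, nan), nan, nan, nan, nan, nan, nan, nan,
                   nan, missing=True)


def compute_region_features(patch: np.ndarray, mask: np.ndarray,
                            pixel_size: float = 1.0) -> RegionFeatures:
    """Area, axes, orientation, circularity and intensity statistics.

    An empty mask returns a fully-missing record (never zero-filled).
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        return RegionFeatures.empty()
    patch = np.asarray(patch, float)
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    # second central moments with the 1/12 pixel-area correction used for
    # the equivalent ellipse of a rasterized region
    mu_rr = (dy * dy).mean() + 1.0 / 12.0
    mu_cc = (dx * dx).mean() + 1.0 / 12.0
    mu_rc = (dy * dx).mean()
    common = math.sqrt((mu_rr - mu_cc) ** 2 + 4.0 * mu_rc ** 2)
    major = 4.0 * math.sqrt(max((mu_rr + mu_cc + common) / 2.0, 0.0))
    minor = 4.0 * math.sqrt(max((mu_rr + mu_cc - common) / 2.0, 0.0))
    orientation = wrap_axial(
        0.5 * math.degrees(math.atan2(2.0 * mu_rc, mu_cc - mu_rr)))
    perim = boundary_contour_length(mask)
    circ = 4.0 * math.pi * n / perim ** 2 if perim > 0 else float("nan")
    vals = patch[mask]
    return RegionFeatures(
        area=n * pixel_size ** 2, area_px=float(n), centroid=(cy, cx),
        major_axis=major * pixel_size, minor_axis=minor * pixel_size,
        orientation=float(orientation), circularity=float(circ),
        mean_int=float(vals.mean()), std_int=float(vals.std()),
        max_int=float(vals.max()), min_int=float(vals.min()))


# ---------------------------------------------------------------------------
# Haralick texture
# ---------------------------------------------------------------------------

@dataclass
class GLCM:
    matrix: np.ndarray         # (levels, levels) pair counts
    offset: tuple[int, int]


def quantize(patch: np.ndarray, levels: int = 64) -> np.ndarray:
    """Quantize intensities to ``levels`` uniform bins over the patch range."""
    patch = np.asarray(patch, float)
    mn, mx = patch.min(), patch.max()
    if mx == mn:
        return np.zeros(patch.shape, dtype=np.intp)
    q = np.floor((patch - mn) / (mx - mn) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(patch: np.ndarray, mask: np.ndarray, levels: int = 64,
                 offset: tuple[int, int] = (0, 1),
                 prequantized: bool = False) -> GLCM:
    """Co-occurrence counts of quantized levels for one pixel offset.

    Only pairs with **both** pixels inside the mask are counted, removing
    background-to-foreground and background-to-background transitions.  No
    symmetrization is applied beyond the chosen offset set.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("GLCM needs a mask with at least 2 pixels")
    q = (np.asarray(patch, np.intp) if prequantized
         else quantize(patch, levels))
    dy, dx = offset
    h, w = q.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys2 = slice(max(0, dy), min(h, h + dy))
    xs2 = slice(max(0, dx), min(w, w + dx))
    a, b = q[ys, xs], q[ys2, xs2]
    both = mask[ys, xs] & mask[ys2, xs2]
    matrix = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(matrix, (a[both], b[both]), 1)
    return GLCM(matrix=matrix, offset=(dy, dx))


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_statistics(glcm: GLCM) -> dict[str, float]:
    """The 13 primary Haralick statistics of one normalized GLCM."""
    total = glcm.matrix.sum()
    if total == 0:
        return {name: float("nan") for name in HARALICK_NAMES}
    p = glcm.matrix.astype(float) / total
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sig_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))

    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=2 * levels - 1)
    p_diff = np.bincount(np.abs(ii - jj).astype(int).ravel(),
                         weights=p.ravel(), minlength=levels)
    k_sum = np.arange(len(p_sum), dtype=float)
    k_diff = np.arange(len(p_diff), dtype=float)

    out: dict[str, float] = {}
    out["asm"] = float((p * p).sum())
    out["contrast"] = float((k_diff ** 2 * p_diff).sum())
    if sig_x > 0 and sig_y > 0:
        out["correlation"] = float(
            ((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        # degenerate matrix (single nonzero cell): correlation undefined
        out["correlation"] = float("nan")
    out["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    out["idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy2(p_sum)
    hxy = _entropy2(p.ravel())
    out["entropy"] = hxy
    mean_diff = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(((k_diff - mean_diff) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy2(p_diff)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx, hy = _entropy2(px), _entropy2(py)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 0 else float("nan")
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


def haralick_features(glcms: list[GLCM]) -> dict[str, float]:
    """Haralick statistics averaged over the offset set (order-invariant)."""
    if not glcms:
        raise ValueError("need at least one GLCM")
    stats = [haralick_statistics(g) for g in glcms]
    return {name: float(np.mean([s[name] for s in stats]))
            for name in HARALICK_NAMES}


def haralick_from_patch(patch: np.ndarray, mask: np.ndarray,
                        levels: int = 64,
                        offsets=DEFAULT_OFFSETS) -> dict[str, float]:
    q = quantize(patch, levels)
    glcms = [compute_glcm(q, mask, levels, off, prequantized=True)
             for off in offsets]
    return haralick_features(glcms)


# ---------------------------------------------------------------------------
# second channel
# ---------------------------------------------------------------------------

@dataclass
class SecondChannelFeatures:
    mean_int: float
    std_int: float
    max_int: float
    max_int_displacement: float   # px from chromatin-mask centroid
    region: str
    radius: int
    missing: bool = False


def second_channel_features(patch2: np.ndarray, mask: np.ndarray,
                            radius: int = 15,
                            region: str = "toroid") -> SecondChannelFeatures:
    """Intensity statistics on a region derived from the chromatin mask.

    ``region`` is the mask dilated or eroded with a disk of ``radius`` px,
    or their set difference (``toroid`` = dilated minus eroded) - the
    convention used for spindle-channel readouts around the chromatin mass.
    ``max_int_displacement`` is the distance of the region's intensity
    argmax to the chromatin-mask centroid.
    """
    mask = np.asarray(mask, bool)
    if region not in ("dilated", "eroded", "toroid"):
        raise ValueError(f"unknown region '{region}'")
    if not mask.any():
        return SecondChannelFeatures(*(float("nan"),) * 4, region, radius,
                                     missing=True)
    footprint = disk(radius)
    dil = ndi.binary_dilation(mask, structure=footprint)
    ero = ndi.binary_erosion(mask, structure=footprint)
    reg = {"dilated": dil, "eroded": ero, "toroid": dil & ~ero}[region]
    if not reg.any():
        return SecondChannelFeatures(*(float("nan"),) * 4, region, radius,
                                     missing=True)
    patch2 = np.asarray(patch2, float)
    vals = patch2[reg]
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    ry, rx = np.nonzero(reg)
    k = int(np.argmax(patch2[reg]))
    disp = math.hypot(ry[k] - cy, rx[k] - cx)
    return SecondChannelFeatures(
        mean_int=float(vals.mean()), std_int=float(vals.std()),
        max_int=float(vals.max()), max_int_displacement=float(disp),
        region=region, radius=radius)


# ---------------------------------------------------------------------------
# trajectory-level geometry
# ---------------------------------------------------------------------------

def sister_distance(centroids_a: np.ndarray, centroids_b: np.ndarray,
                    pixel_size: float = 1.0,
                    division_index: int = 0) -> np.ndarray:
    """Per-frame Euclidean sister centroid distance in um.

    Pre-division frames (before ``division_index``) are 0 by definition -
    there is only a single chromatin mass.
    """
    a = np.asarray(centroids_a, float)
    b = np.asarray(centroids_b, float)
    if a.shape != b.shape:
        raise ValueError("sibling trajectories must share frames")
    d = np.linalg.norm(a - b, axis=1) * pixel_size
    d[:division_index] = 0.0
    return d


def angular_features(orientation_deg: np.ndarray, ip_index: int,
                     ma_index: int, reference_axis_deg: float
                     ) -> tuple[float, float]:
    """Plate-rotation readouts over the mitotic window [IP, MA).

    Returns ``(sum_abs_angular_change, mean_angular_difference)`` in
    degrees: the summed absolute per-step orientation change of the
    chromatin mass, and the mean absolute axial difference between the mass
    orientation and the sister-separation axis at MA.  Angles are axial, so
    a step across the +-90 wrap (88 -> -88) contributes 4 degrees, not 176.
    Fewer than 2 frames between the anchors yields NaN.
    """
    theta = np.asarray(orientation_deg, float)[ip_index:ma_index]
    if len(theta) < 2:
        return float("nan"), float("nan")
    steps = wrap_axial(np.diff(theta))
    sum_abs = float(np.abs(steps).sum())
    mean_diff = float(np.abs(wrap_axial(theta - reference_axis_deg)).mean())
    return sum_abs, mean_diff
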