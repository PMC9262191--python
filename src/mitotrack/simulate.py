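"""Synthetic 2D+t chromatin movies with complete ground truth.

The generator emulates the nuclear dynamics a mitotic-progression pipeline
measures: interphase nuclei rendered as smooth elliptical intensity
profiles, chromatin condensation at mitotic entry (area drops by the square
of the shrink factor while mean intensity rises by a configurable gain),
formation of an elongated metaphase plate whose orientation may oscillate,
anaphase separation of the two sister chromatin masses along a random
division axis with linear pole displacement, and telophase decondensation
easing both daughters back to interphase statistics.  An optional second
channel renders a spindle-like signal (two pole foci plus a bridge) during
mitosis.

Intensities are smooth super-Gaussian radial profiles rather than binary
disks so that threshold- and watershed-based segmentation are non-trivially
exercised.  Cells move with small Gaussian random walks so tracking is
exercised but unambiguous at the default density.

Ground-truth states follow the 0/1/2/3 convention used by the
synchronization module: 1 interphase, 2 prophase through early anaphase,
3 late anaphase/telophase; the IP anchor is the first state-2 frame and the
MA anchor the first state-3 frame (equal to the division frame, the first
frame at which the two sister masses exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .io import MovieStack

U16_MAX = 65535

#: mean of exp(-r^4) over the unit disk; mean in-mask intensity of the
#: default profile is background + amplitude * this constant
PROFILE_MEAN = 0.74076


class SimulationError(ValueError):
    """Invalid simulation configuration (e.g. overlapping cells)."""


@dataclass
class SimParams:
    """Study conditions for one synthetic movie.

    Defaults describe a HeLa-like field at 0.65 um/px and 3 min/frame:
    20 nuclei of ~11 px semi-major axis, five divisions placed so the
    default 30/60-frame extraction window fits, condensation shrinking each
    axis to 0.6x with a 1.4x intensity gain, sisters separating at
    1.5 px/frame from an initial 12 px offset, and telophase recovery over
    20 frames.
    """

    image_size: tuple[int, int] = (600, 600)
    n_frames: int = 120
    sampling_interval: float = 3.0     # minutes/frame
    pixel_size: float = 0.65           # um/pixel
    n_cells: int = 20
    n_divisions: int = 5
    division_schedule: list[tuple[int, int]] | None = None
    interphase_radius: float = 11.0    # semi-major axis, px
    axis_ratio: float = 0.8            # semi-minor / semi-major
    prophase_shrink_factor: float = 0.6
    intensity_gain_mitosis: float = 1.4
    prophase_len: int = 10             # frames from IP to division
    plate_start: int = 4               # frames after IP when the plate forms
    initial_separation: float = 12.0   # px, sister distance at division
    anaphase_speed: float = 1.5        # px/frame
    max_separation: float = 26.0       # px, pole displacement saturates here
    recovery_len: int = 20             # frames to return to interphase values
    rotation_amplitude: float = 15.0   # deg, plate oscillation
    rotation_period: float = 8.0       # frames
    drift_sigma: float = 0.5           # px/frame random walk
    interphase_intensity: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    second_channel: bool = True
    profile_power: float = 4.0         # super-Gaussian exponent
    min_before: int = 30
    min_after: int = 60
    margin: int = 45                   # px kept free near the image border
    min_spacing: float = 70.0          # px between cell centres at placement
    seed: int = 0

    def resolved_schedule(self) -> list[tuple[int, int]]:
        if self.division_schedule is not None:
            return list(self.division_schedule)
        lo = self.min_before + 2
        hi = self.n_frames - self.min_after - 2
        if self.n_divisions == 0:
            return []
        frames = np.linspace(lo, max(lo, hi), self.n_divisions)
        return [(i + 1, int(round(f))) for i, f in enumerate(frames)]

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_cells < 1:
            raise SimulationError("n_frames and n_cells must be >= 1")
        if not (0 < self.prophase_shrink_factor < 1):
            raise SimulationError("prophase_shrink_factor must be in (0, 1)")
        if self.intensity_gain_mitosis <= 1:
            raise SimulationError("intensity_gain_mitosis must be > 1")
        if self.interphase_radius <= 0 or self.noise_sd < 0:
            raise SimulationError("radii must be > 0 and noise_sd >= 0")
        seen = set()
        for cid, frame in self.resolved_schedule():
            if not (1 <= cid <= self.n_cells):
                raise SimulationError(f"division schedule names unknown cell {cid}")
            if cid in seen:
                raise SimulationError(f"cell {cid} divides twice")
            seen.add(cid)
            if not (self.min_before <= frame < self.n_frames - self.min_after):
                raise SimulationError(
                    f"division frame {frame} outside "
                    f"[{self.min_before}, {self.n_frames - self.min_after})")
            if frame - self.prophase_len < 1:
                raise SimulationError(
                    f"division at {frame} leaves no interphase before IP")


@dataclass
class GroundTruth:
    """Per-frame and per-cell ground truth of a generated movie.

    ``frames`` has one row per live cell per frame (frame, cell_id, y, x,
    state); ``cells`` one row per cell (cell_id, parent_id, division_frame,
    ip_frame, ma_frame) with -1 for "not applicable"; ``labels`` is the
    ``(T, H, W)`` instance label movie (0 = background, else cell_id).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame
    labels: np.ndarray

    def centroids(self, cell_id: int) -> pd.DataFrame:
        return self.frames[self.frames.cell_id == cell_id].set_index("frame")

    def live_counts(self) -> pd.Series:
        return self.frames.groupby("frame").size()


# ---------------------------------------------------------------------------
# geometry of one cell through mitosis
# ---------------------------------------------------------------------------

@dataclass
class _Blob:
    cell_id: int
    cy: float
    cx: float
    a: float
    b: float
    theta: float      # deg, major axis from +x (col) toward +y (row)
    amp: float
    state: int


def _separation(p: SimParams, t_after_division: int) -> float:
    return min(p.initial_separation + p.anaphase_speed * t_after_division,
               p.max_separation)


def separation_series(p: SimParams, division_frame: int,
                      frames: np.ndarray) -> np.ndarray:
    """Analytic sister centroid distance (px) per frame; 0 pre-division."""
    out = np.zeros(len(frames), float)
    for i, t in enumerate(frames):
        if t >= division_frame:
            out[i] = _separation(p, t - division_frame)
    return out


def _place_cells(rng: np.random.Generator, p: SimParams) -> np.ndarray:
    h, w = p.image_size
    m = p.margin
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        raise SimulationError("image too small for the configured margin")
    placed: list[np.ndarray] = []
    for _ in range(p.n_cells):
        for _attempt in range(5000):
            pt = rng.uniform([m, m], [h - m, w - m])
            if all(np.hypot(*(pt - q)) >= p.min_spacing for q in placed):
                placed.append(pt)
                break
        else:
            raise SimulationError(
                f"could not place {p.n_cells} cells with spacing "
                f"{p.min_spacing} on a {p.image_size} image")
    return np.array(placed)


def _cell_blobs(p: SimParams, t: int, cell: dict) -> list[_Blob]:
    """Appearance of one (possibly divided) cell lineage at frame t."""
    cy, cx = cell["path"][t]
    a0, b0, theta0 = cell["a"], cell["b"], cell["theta"]
    base = p.interphase_intensity
    d = cell["division_frame"]
    if d is None or t < cell["ip_frame"]:
        return [_Blob(cell["id"], cy, cx, a0, b0, theta0, base, 1)]

    ip = cell["ip_frame"]
    gain = p.intensity_gain_mitosis
    r_full = math.sqrt(a0 * b0) * p.prophase_shrink_factor
    if t < d:
        # condensation is a step at the IP frame: state 2 means condensed
        amp = base * gain
        if t < ip + p.plate_start:
            r = math.sqrt(a0 * b0) * p.prophase_shrink_factor
            return [_Blob(cell["id"], cy, cx, r, r, theta0, amp, 2)]
        # metaphase plate, perpendicular to the future separation axis
        rot = p.rotation_amplitude * math.sin(
            2 * math.pi * (t - ip) / p.rotation_period)
        theta = cell["div_axis"] + 90.0 + rot
        return [_Blob(cell["id"], cy, cx, 1.8 * r_full, 0.45 * r_full,
                      theta, base * gain, 2)]

    # two daughters separating and decondensing
    sep = _separation(p, t - d)
    u = min(1.0, (t - d) / p.recovery_len)
    r_d = 0.9 * r_full
    a_t = r_d + u * (a0 - r_d)
    b_t = r_d + u * (b0 - r_d)
    amp = base * (gain - u * (gain - 1))
    phi = math.radians(cell["div_axis"])
    dy, dx = math.sin(phi) * sep / 2, math.cos(phi) * sep / 2
    ids = cell["daughter_ids"]
    return [
        _Blob(ids[0], cy - dy, cx - dx, a_t, b_t, cell["div_axis"], amp, 3),
        _Blob(ids[1], cy + dy, cx + dx, a_t, b_t, cell["div_axis"], amp, 3),
    ]


def _render_profile(img: np.ndarray, blob: _Blob, power: float,
                    labels: np.ndarray | None) -> None:
    h, w = img.shape
    rmax = 2.2 * max(blob.a, blob.b)
    y0 = max(0, int(blob.cy - rmax))
    y1 = min(h, int(blob.cy + rmax) + 2)
    x0 = max(0, int(blob.cx - rmax))
    x1 = min(w, int(blob.cx + rmax) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - blob.cy
    dx = xx - blob.cx
    th = math.radians(blob.theta)
    u = (dx * math.cos(th) + dy * math.sin(th)) / blob.a
    v = (-dx * math.sin(th) + dy * math.cos(th)) / blob.b
    u2 = u * u + v * v
    img[y0:y1, x0:x1] += blob.amp * np.exp(-u2 ** (power / 2.0))
    if labels is not None:
        mask = u2 <= 1.0
        sub = labels[y0:y1, x0:x1]
        if np.any(sub[mask] != 0):
            raise SimulationError(
                f"cell masks overlap at ({blob.cy:.0f}, {blob.cx:.0f}); "
                "the configured schedule/placement is invalid")
        sub[mask] = blob.cell_id


def _render_spindle(img: np.ndarray, p: SimParams, t: int, cell: dict,
                    blobs: list[_Blob]) -> None:
    if cell["division_frame"] is None or t < cell["ip_frame"]:
        # faint diffuse interphase signal
        b = blobs[0]
        _render_profile(img, replace(b, amp=12.0), 2.0, None)
        return
    d = cell["division_frame"]
    cy, cx = cell["path"][t]
    r_full = math.sqrt(cell["a"] * cell["b"]) * p.prophase_shrink_factor
    length = _separation(p, t - d) if t >= d else 2.4 * r_full
    phi = math.radians(cell["div_axis"])
    dy, dx = math.sin(phi) * length / 2, math.cos(phi) * length / 2
    for sgn in (-1, 1):  # pole foci
        _render_profile(img, _Blob(0, cy + sgn * dy, cx + sgn * dx,
                                   2.5, 2.5, 0.0, 55.0, 0), 2.0, None)
    _render_profile(img, _Blob(0, cy, cx, length / 2 + 2.0, 0.5 * r_full,
                               cell["div_axis"], 35.0, 0), 2.0, None)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_movie(params: SimParams) -> tuple[MovieStack, GroundTruth]:
    """Render a movie and its ground truth; deterministic for a fixed seed."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size
    n = p.n_cells
    schedule = dict((cid, f) for cid, f in p.resolved_schedule())

    centers = _place_cells(rng, p)
    a = p.interphase_radius * rng.uniform(0.95, 1.05, n)
    b = a * p.axis_ratio
    theta = rng.uniform(-90.0, 90.0, n)
    div_axis = rng.uniform(0.0, 180.0, n)
    steps = rng.normal(0.0, p.drift_sigma, (p.n_frames, n, 2))
    steps[0] = 0.0
    paths = centers[None, :, :] + np.cumsum(steps, axis=0)

    cells = []
    next_id = n + 1
    for i in range(n):
        cid = i + 1
        d = schedule.get(cid)
        cell = {
            "id": cid, "a": a[i], "b": b[i], "theta": theta[i],
            "div_axis": div_axis[i], "path": paths[:, i, :],
            "division_frame": d,
            "ip_frame": (d - p.prophase_len) if d is not None else None,
            "daughter_ids": None,
        }
        if d is not None:
            cell["daughter_ids"] = (next_id, next_id + 1)
            next_id += 2
        cells.append(cell)

    chrom = np.empty((p.n_frames, h, w), np.uint16)
    second = np.empty((p.n_frames, h, w), np.uint16) if p.second_channel else None
    labels = np.zeros((p.n_frames, h, w), np.uint16)
    rows: list[tuple] = []

    for t in range(p.n_frames):
        img = np.full((h, w), float(p.background_level))
        img2 = np.full((h, w), 5.0) if p.second_channel else None
        for cell in cells:
            blobs = _cell_blobs(p, t, cell)
            for blob in blobs:
                _render_profile(img, blob, p.profile_power, labels[t])
                rows.append((t, blob.cell_id, blob.cy, blob.cx, blob.state))
            if img2 is not None:
                _render_spindle(img2, p, t, cell, blobs)
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, (h, w))
            if img2 is not None:
                img2 = img2 + rng.normal(0.0, p.noise_sd, (h, w))
        chrom[t] = np.clip(np.round(img), 0, U16_MAX).astype(np.uint16)
        if img2 is not None:
            second[t] = np.clip(np.round(img2), 0, U16_MAX).astype(np.uint16)

    frames = pd.DataFrame(rows, columns=["frame", "cell_id", "y", "x", "state"])
    cell_rows = []
    for cell in cells:
        d = cell["division_frame"]
        if d is None:
            cell_rows.append((cell["id"], -1, -1, -1, -1))
        else:
            ip, ma = cell["ip_frame"], d
            cell_rows.append((cell["id"], -1, d, ip, ma))
            for did in cell["daughter_ids"]:
                cell_rows.append((did, cell["id"], d, ip, ma))
    cells_df = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "parent_id", "division_frame", "ip_frame", "ma_frame"])

    channels = {"chromatin": chrom}
    if second is not None:
        channels["second"] = second
    movie = MovieStack(channels, pixel_size=p.pixel_size,
                       sampling_interval=p.sampling_interval,
                       metadata={"microscope": "synthetic",
                                 "experiment_id": "sim",
                                 "plate": "1", "position": "1",
                                 "treatment": "none"})
    return movie, GroundTruth(frames=frames, cells=cells_df, labels=labels)


def write_fixture(movie: MovieStack, truth: GroundTruth, directory,
                  write_labels: bool = False) -> list[Path]:
    """Write per-frame TIFFs (``<channel>_t%04d.tif``) and truth CSVs.

    Lexicographic filename order equals temporal order.  Returns the list of
    written paths; I/O failures surface with the offending path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, arr in movie.channels.items():
            for t in range(arr.shape[0]):
                path = directory / f"{name}_t{t:04d}.tif"
                tifffile.imwrite(path, arr[t])
                written.append(path)
        if write_labels:
            for t in range(truth.labels.shape[0]):
                path = directory / f"labels_t{t:04d}.tif"
                tifffile.imwrite(path, truth.labels[t])
                written.append(path)
        fpath = directory / "truth_frames.csv"
        truth.frames.to_csv(fpath, index=False)
        written.append(fpath)
        cpath = directory / "truth_cells.csv"
        truth.cells.to_csv(cpath, index=False)
        written.append(cpath)
    except OSError as exc:
        raise IOError(f"failed writing fixture under {directory}: {exc}") from exc
    return written
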