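"""Calibrated image series, the analysis project container and table export.

Conventions used throughout the package (asserted here, relied on everywhere):
coordinates are 0-based ``(row, col) = (y, x)``; frame indices are 0-based;
all frame windows are half-open ``[start, end)``.  Image data are normalized
to unsigned 16-bit on import; 8-bit inputs are upcast without rescaling.
"""

from __future__ import annotations

import glob as _glob
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = 1

#: metadata keys every project carries (free-form strings)
META_KEYS = ("microscope", "experiment_id", "plate", "position", "treatment")


class ProjectIOError(IOError):
    """Raised when a project file cannot be read or is inconsistent."""


# ---------------------------------------------------------------------------
# MovieStack
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """A calibrated 2D+t movie with one mandatory chromatin channel.

    Parameters
    ----------
    channels
        Mapping of channel name to a ``(T, H, W)`` intensity array.  The
        first channel is the chromatin channel; an optional second channel
        (e.g. a tubulin marker) must match it in frame count and dimensions.
    pixel_size
        Lateral calibration in micrometres per pixel.
    sampling_interval
        Time between consecutive frames in minutes.
    metadata
        Free-form acquisition metadata (microscope, experiment_id, plate,
        position, treatment, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.65
    sampling_interval: float = 3.0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 2:
            raise ValueError("a MovieStack holds one or two channels, got "
                             f"{len(self.channels)}")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        first = next(iter(self.channels.values()))
        if first.ndim != 3 or first.shape[0] < 1:
            raise ValueError("channels must be (T, H, W) arrays with T >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @property
    def frame_count(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def chromatin(self) -> np.ndarray:
        return next(iter(self.channels.values()))

    @property
    def second(self) -> np.ndarray | None:
        names = list(self.channels)
        return self.channels[names[1]] if len(names) == 2 else None


_digit_re = re.compile(r"(\d+)")


def natural_sort_key(name) -> tuple:
    """Sort key treating digit runs as integers, so t2 < t10."""
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in _digit_re.split(str(name)))


def _as_uint16(arr: np.ndarray, origin: str) -> np.ndarray:
    if arr.dtype == np.uint16:
        return arr
    if arr.dtype == np.uint8:
        # upcast without rescaling: 8-bit value v stays v
        return arr.astype(np.uint16)
    if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating):
        clipped = np.clip(arr, 0, np.iinfo(np.uint16).max)
        return np.round(clipped).astype(np.uint16)
    raise ValueError(f"unsupported image dtype {arr.dtype} in {origin}")


def _read_channel(files: list[Path], channel: str) -> np.ndarray:
    frames: list[np.ndarray] = []
    shape = None
    for f in files:
        arr = tifffile.imread(f)
        pages = arr[None] if arr.ndim == 2 else arr
        if pages.ndim != 3:
            raise ValueError(f"{f}: expected 2D frames, got shape {arr.shape}")
        for page in pages:
            if shape is None:
                shape = page.shape
            elif page.shape != shape:
                raise ValueError(
                    f"channel '{channel}': frame dimensions {page.shape} in "
                    f"{f} differ from {shape}")
            frames.append(_as_uint16(page, str(f)))
    return np.stack(frames)


def import_image_series(channel_files: dict[str, str | list],
                        pixel_size: float = 0.65,
                        sampling_interval: float = 3.0,
                        metadata: dict[str, str] | None = None) -> MovieStack:
    """Read one or two TIFF series into a :class:`MovieStack`.

    ``channel_files`` maps the channel name to either a glob pattern or an
    explicit list of paths.  Frames are ordered by natural sort of the
    filenames, so ``t0003, t0001, t0002`` yields temporal order 1, 2, 3.
    Both channels must agree in frame count and dimensions; a mismatch is
    rejected naming the offending channel.
    """
    arrays: dict[str, np.ndarray] = {}
    for channel, spec in channel_files.items():
        if isinstance(spec, (str, Path)):
            files = [Path(p) for p in _glob.glob(str(spec))]
        else:
            files = [Path(p) for p in spec]
        if not files:
            raise ValueError(f"channel '{channel}': no input files")
        files.sort(key=natural_sort_key)
        arrays[channel] = _read_channel(files, channel)
    counts = {c: a.shape[0] for c, a in arrays.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"channels have different frame counts: {counts}")
    return MovieStack(arrays, pixel_size=pixel_size,
                      sampling_interval=sampling_interval,
                      metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# Project
# ---------------------------------------------------------------------------

@dataclass
class Project:
    """Per-cell feature time series, single features, states and metadata.

    All time-series arrays are ``(n_cells, T)`` where ``T = n_before +
    n_after`` is the common trajectory window length; single features are
    ``(n_cells,)``.  ``states`` holds the per-frame mitotic state label
    (0 invalid, 1 interphase, 2 prophase..early anaphase, 3 late
    anaphase/telophase); ``ip``/``ma`` are the anchor frame indices within
    the window (-1 when invalid).
    """

    ts: dict[str, np.ndarray] = field(default_factory=dict)
    singles: dict[str, np.ndarray] = field(default_factory=dict)
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    states: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), np.int8))
    ip: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ma: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    valid: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    n_before: int = 30
    n_after: int = 60
    pixel_size: float = 0.65
    sampling_interval: float = 3.0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, t = self.n_cells, self.window_length
        for name, arr in self.ts.items():
            if arr.shape != (n, t):
                raise ValueError(
                    f"time series '{name}' has shape {arr.shape}, expected {(n, t)}")
        for name, arr in self.singles.items():
            if arr.shape != (n,):
                raise ValueError(f"single feature '{name}' has shape {arr.shape}")

    @property
    def n_cells(self) -> int:
        return len(self.meta)

    @property
    def window_length(self) -> int:
        return self.n_before + self.n_after

    @property
    def feature_names(self) -> list[str]:
        return sorted(self.ts)

    @property
    def single_names(self) -> list[str]:
        return sorted(self.singles)


def save_project(project: Project, path) -> None:
    """Write a project to a single hierarchical HDF5 file (lossless)."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as h5:
            h5.attrs["schema_version"] = SCHEMA_VERSION
            h5.attrs["n_before"] = project.n_before
            h5.attrs["n_after"] = project.n_after
            h5.attrs["pixel_size"] = project.pixel_size
            h5.attrs["sampling_interval"] = project.sampling_interval
            h5.attrs["config_json"] = json.dumps(project.config)
            g = h5.create_group("ts")
            for name, arr in project.ts.items():
                g.create_dataset(name, data=arr)
            g = h5.create_group("singles")
            for name, arr in project.singles.items():
                g.create_dataset(name, data=arr)
            g = h5.create_group("sync")
            g.create_dataset("states", data=project.states)
            g.create_dataset("ip", data=project.ip)
            g.create_dataset("ma", data=project.ma)
            g.create_dataset("valid", data=project.valid.astype(np.uint8))
            g = h5.create_group("meta")
            g.attrs["columns"] = json.dumps(list(project.meta.columns))
            for col in project.meta.columns:
                vals = project.meta[col].astype(str).to_numpy()
                g.create_dataset(col, data=vals.astype(h5py.string_dtype()))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise ProjectIOError(f"cannot write project file {path}: {exc}") from exc


def load_project(path) -> Project:
    """Read a project written by :func:`save_project`.

    Truncated or foreign files raise :class:`ProjectIOError`; a schema
    version newer than this library raises as well.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            version = h5.attrs.get("schema_version")
            if version is None:
                raise ProjectIOError(f"{path}: not a mitotrack project file")
            if int(version) > SCHEMA_VERSION:
                raise ProjectIOError(
                    f"{path}: schema version {version} is newer than supported "
                    f"({SCHEMA_VERSION})")
            # feature names may contain '/' (e.g. derived/recovery), which
            # h5py maps to nested groups; walk them back into flat names
            def collect(group) -> dict[str, np.ndarray]:
                out: dict[str, np.ndarray] = {}
                group.visititems(
                    lambda name, obj: out.__setitem__(name, np.asarray(obj))
                    if isinstance(obj, h5py.Dataset) else None)
                return out

            ts = collect(h5["ts"])
            singles = collect(h5["singles"])
            sync = h5["sync"]
            states = np.asarray(sync["states"], dtype=np.int8)
            ip = np.asarray(sync["ip"])
            ma = np.asarray(sync["ma"])
            valid = np.asarray(sync["valid"]).astype(bool)
            cols = json.loads(h5["meta"].attrs["columns"])
            meta = pd.DataFrame({
                col: [v.decode() if isinstance(v, bytes) else str(v)
                      for v in np.asarray(h5["meta"][col])]
                for col in cols
            }, columns=cols)
            return Project(
                ts=ts, singles=singles, meta=meta, states=states,
                ip=ip, ma=ma, valid=valid,
                n_before=int(h5.attrs["n_before"]),
                n_after=int(h5.attrs["n_after"]),
                pixel_size=float(h5.attrs["pixel_size"]),
                sampling_interval=float(h5.attrs["sampling_interval"]),
                config=json.loads(h5.attrs["config_json"]),
            )
    except OSError as exc:
        raise ProjectIOError(f"corrupt or unreadable project file {path}: {exc}") from exc


def fuse_projects(projects: list[Project]) -> Project:
    """Concatenate projects from different positions into one.

    Requires identical feature registries and window lengths; cell count of
    the result is the sum of the inputs and per-cell metadata is preserved
    verbatim.  Fusion is associative up to cell ordering.
    """
    if not projects:
        raise ValueError("fuse_projects needs at least one project")
    first = projects[0]
    for p in projects[1:]:
        if p.feature_names != first.feature_names or p.single_names != first.single_names:
            diff = set(p.feature_names) ^ set(first.feature_names)
            diff |= set(p.single_names) ^ set(first.single_names)
            raise ValueError(
                f"feature registries differ between projects: {sorted(diff)}")
        if (p.n_before, p.n_after) != (first.n_before, first.n_after):
            raise ValueError("projects have different trajectory windows")
    if len(projects) == 1:
        return first

    def cat(key, arrays):
        return np.concatenate(arrays, axis=0)

    ts = {name: cat(name, [p.ts[name] for p in projects]) for name in first.ts}
    singles = {name: cat(name, [p.singles[name] for p in projects])
               for name in first.singles}
    meta = pd.concat([p.meta for p in projects], ignore_index=True)
    return Project(
        ts=ts, singles=singles, meta=meta,
        states=np.concatenate([p.states for p in projects], axis=0),
        ip=np.concatenate([p.ip for p in projects]),
        ma=np.concatenate([p.ma for p in projects]),
        valid=np.concatenate([p.valid for p in projects]),
        n_before=first.n_before, n_after=first.n_after,
        pixel_size=first.pixel_size, sampling_interval=first.sampling_interval,
        config=dict(first.config),
    )


def export_features(project: Project, directory, cell_ids=None,
                    features: list[str] | None = None) -> tuple[Path, Path]:
    """Export feature tables as CSV spreadsheets.

    Writes one long-format table ``features_long.csv`` with columns
    (cell, frame, feature, value) plus the metadata columns, and one
    single-feature table ``features_single.csv`` with (cell, feature, value)
    plus metadata.  Returns the two paths.
    """
    if cell_ids is None:
        cell_ids = np.arange(project.n_cells)
    cell_ids = np.asarray(cell_ids, dtype=int)
    if cell_ids.size == 0:
        raise ValueError("empty selection: nothing to export")
    if features is None:
        features = project.feature_names
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = project.meta.iloc[cell_ids].reset_index(drop=True)
    t = project.window_length
    long_rows = []
    for name in features:
        arr = project.ts[name][cell_ids]
        df = pd.DataFrame({
            "cell": np.repeat(cell_ids, t),
            "frame": np.tile(np.arange(t), len(cell_ids)),
            "feature": name,
            "value": arr.ravel(),
        })
        long_rows.append(df)
    long_df = pd.concat(long_rows, ignore_index=True)
    meta_by_cell = project.meta.copy()
    meta_by_cell["cell"] = np.arange(project.n_cells)
    long_df = long_df.merge(meta_by_cell, on="cell", how="left")
    long_path = directory / "features_long.csv"
    long_df.to_csv(long_path, index=False)

    single_rows = []
    for name in project.single_names:
        arr = project.singles[name][cell_ids]
        single_rows.append(pd.DataFrame({
            "cell": cell_ids, "feature": name, "value": arr}))
    if single_rows:
        single_df = pd.concat(single_rows, ignore_index=True)
        single_df = single_df.merge(meta_by_cell, on="cell", how="left")
    else:
        single_df = pd.DataFrame(columns=["cell", "feature", "value"])
    single_path = directory / "features_single.csv"
    single_df.to_csv(single_path, index=False)
    return long_path, single_path
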