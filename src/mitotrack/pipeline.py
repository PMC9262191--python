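"""End-to-end analysis: movie -> detections -> tracks -> features -> project.

The pipeline detects nuclei in every frame, links them backward in time,
extracts complete mitotic sister-pair trajectories, segments a central-cell
mask for every trajectory frame, computes the feature time series and
single features, synchronizes every pair with the classical pathway (TC3 IP
detection plus distance-threshold MA repositioning) and assembles the
result into a :class:`~mitotrack.io.Project`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import derive
from .detect import detect_movie, make_resolution_preset
from .features import (DEFAULT_OFFSETS, HARALICK_NAMES,
                       angular_features, compute_region_features,
                       haralick_from_patch, second_channel_features,
                       sister_distance)
from .io import META_KEYS, MovieStack, Project
from .segment import crop_patch, default_patch_size, segment_detection
from .sync import classical_sync, ma_threshold_for_pixel_size
from .track import SisterPair, extract_mitotic_trajectories, track_movie

log = logging.getLogger(__name__)

BASIC_FEATURES = ("area", "circularity", "major_axis", "minor_axis",
                  "axis_ratio", "orientation", "mean_int", "std_int",
                  "max_int", "min_int")


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end run (resolution-aware defaults).

    ``sigma_range``, ``patch_size`` and ``ma_threshold_px`` default to
    presets derived from the movie's pixel size (13 um expected nucleus
    diameter; 96 px patches and a 10 px MA threshold at 0.65 um/px).
    """

    sigma_range: tuple[float, float] | None = None
    threshold_rel: float = 0.1
    n_scales: int = 6
    cutoff: float | str = "auto"
    fallback_cutoff: float = 50.0
    n_before: int = 30
    n_after: int = 60
    patch_size: int | None = None
    center_fraction: float = 0.5
    ma_threshold_px: float | None = None
    haralick: bool = True
    second_channel: bool = True
    second_channel_radius: int = 15
    smooth_window: int = 5
    expected_diameter_um: float = 13.0

    def resolve(self, movie: MovieStack) -> "PipelineConfig":
        cfg = PipelineConfig(**vars(self))
        if cfg.sigma_range is None:
            cfg.sigma_range, _ = make_resolution_preset(
                movie.pixel_size, cfg.expected_diameter_um)
        if cfg.patch_size is None:
            cfg.patch_size = default_patch_size(movie.pixel_size)
        if cfg.ma_threshold_px is None:
            cfg.ma_threshold_px = ma_threshold_for_pixel_size(movie.pixel_size)
        return cfg

    def as_dict(self) -> dict:
        d = dict(vars(self))
        d["sigma_range"] = list(self.sigma_range) if self.sigma_range else None
        return d


def _trajectory_features(movie: MovieStack, pair: SisterPair,
                         cfg: PipelineConfig,
                         label_images: np.ndarray | None):
    """Per-frame feature series for both daughters of one sister pair."""
    chrom = movie.chromatin
    second = movie.second if cfg.second_channel else None
    px = movie.pixel_size
    t_win = pair.a.window_length
    out = {}
    for traj in (pair.a, pair.b):
        series: dict[str, np.ndarray] = {
            name: np.full(t_win, np.nan) for name in BASIC_FEATURES}
        if cfg.haralick:
            for name in HARALICK_NAMES:
                series[f"haralick_{name}"] = np.full(t_win, np.nan)
        if second is not None:
            for name in ("ch2_mean_int_toroid", "ch2_std_int_toroid",
                         "ch2_max_int_dilated", "ch2_max_displacement"):
                series[name] = np.full(t_win, np.nan)
        centroids = np.full((t_win, 2), np.nan)
        n_ok = 0
        for i, (frame, center) in enumerate(zip(traj.frames, traj.centroids)):
            labels = label_images[frame] if label_images is not None else None
            patch = segment_detection(chrom[frame], center, cfg.patch_size,
                                      cfg.center_fraction, label_image=labels)
            if not patch.ok:
                continue
            n_ok += 1
            rf = compute_region_features(patch.image, patch.mask, px)
            series["area"][i] = rf.area
            series["circularity"][i] = rf.circularity
            series["major_axis"][i] = rf.major_axis
            series["minor_axis"][i] = rf.minor_axis
            series["axis_ratio"][i] = (rf.minor_axis / rf.major_axis
                                       if rf.major_axis else np.nan)
            series["orientation"][i] = rf.orientation
            series["mean_int"][i] = rf.mean_int
            series["std_int"][i] = rf.std_int
            series["max_int"][i] = rf.max_int
            series["min_int"][i] = rf.min_int
            centroids[i] = (patch.origin[0] + rf.centroid[0],
                            patch.origin[1] + rf.centroid[1])
            if cfg.haralick:
                try:
                    har = haralick_from_patch(patch.image, patch.mask,
                                              offsets=DEFAULT_OFFSETS)
                    for name, val in har.items():
                        series[f"haralick_{name}"][i] = val
                except ValueError:
                    pass
            if second is not None:
                patch2, _ = crop_patch(second[frame], center, cfg.patch_size)
                tor = second_channel_features(
                    patch2, patch.mask, cfg.second_channel_radius, "toroid")
                dil = second_channel_features(
                    patch2, patch.mask, cfg.second_channel_radius, "dilated")
                series["ch2_mean_int_toroid"][i] = tor.mean_int
                series["ch2_std_int_toroid"][i] = tor.std_int
                series["ch2_max_int_dilated"][i] = dil.max_int
                series["ch2_max_displacement"][i] = dil.max_int_displacement
        out[traj.daughter] = (series, centroids, n_ok)
    return out


def run_pipeline(movie: MovieStack, config: PipelineConfig | None = None,
                 label_images: np.ndarray | None = None) -> Project:
    """Run the complete analysis and return the assembled project."""
    cfg = (config or PipelineConfig()).resolve(movie)
    detections = detect_movie(movie.chromatin, cfg.sigma_range,
                              cfg.threshold_rel, cfg.n_scales)
    graph = track_movie(detections, cutoff=cfg.cutoff,
                        fallback_cutoff=cfg.fallback_cutoff)
    pairs = extract_mitotic_trajectories(graph, cfg.n_before, cfg.n_after)
    log.info("tracked %d divisions, extracted %d complete sister pairs",
             len(graph.divisions), len(pairs))
    return build_project(movie, pairs, cfg, label_images)


def build_project(movie: MovieStack, pairs: list[SisterPair],
                  cfg: PipelineConfig,
                  label_images: np.ndarray | None = None) -> Project:
    """Assemble features, synchronization and metadata for extracted pairs."""
    cfg = cfg.resolve(movie)
    t_win = cfg.n_before + cfg.n_after
    cells: list[dict] = []
    meta_rows: list[dict] = []
    base_meta = {k: str(movie.metadata.get(k, "")) for k in META_KEYS}

    for p_idx, pair in enumerate(pairs):
        per_daughter = _trajectory_features(movie, pair, cfg, label_images)
        dist_px = pair.sister_distance_px()
        feats_a = per_daughter["a"][0]
        tc3 = np.column_stack([feats_a["area"], feats_a["circularity"],
                               feats_a["mean_int"], feats_a["std_int"]])
        sync = classical_sync(tc3, dist_px, pair.a.division_index,
                              ma_threshold_px=cfg.ma_threshold_px)
        sum_ang, mean_ang = np.nan, np.nan
        if sync.valid:
            axis_vec = pair.b.centroids[sync.ma_index] - \
                pair.a.centroids[sync.ma_index]
            ref_axis = np.degrees(np.arctan2(axis_vec[0], axis_vec[1]))
            sum_ang, mean_ang = angular_features(
                feats_a["orientation"], sync.ip_index, sync.ma_index, ref_axis)
        dist_um = sister_distance(pair.a.centroids, pair.b.centroids,
                                  movie.pixel_size, pair.a.division_index)
        for traj in (pair.a, pair.b):
            series, _centroids, n_ok = per_daughter[traj.daughter]
            series = dict(series)
            series["sister_distance"] = dist_um
            singles = {
                "division_frame": float(traj.division_frame),
                "ip_to_ma_minutes": (
                    (sync.ma_index - sync.ip_index) * movie.sampling_interval
                    if sync.valid else np.nan),
                "sum_abs_angular_change": sum_ang,
                "mean_angular_difference": mean_ang,
                "segmented_fraction": n_ok / t_win,
            }
            cells.append({"series": series, "singles": singles, "sync": sync,
                          "pair": p_idx, "daughter": traj.daughter,
                          "track_id": traj.track_id})
            meta_rows.append({**base_meta,
                              "cell_id": f"pair{p_idx}{traj.daughter}",
                              "pair": str(p_idx),
                              "daughter": traj.daughter,
                              "track_id": str(traj.track_id)})

    n = len(cells)
    ts_names = sorted(cells[0]["series"]) if cells else []
    single_names = sorted(cells[0]["singles"]) if cells else []
    ts = {name: np.full((n, t_win), np.nan) for name in ts_names}
    singles = {name: np.full(n, np.nan) for name in single_names}
    states = np.zeros((n, t_win), np.int8)
    ip = np.full(n, -1, dtype=np.int64)
    ma = np.full(n, -1, dtype=np.int64)
    valid = np.zeros(n, bool)
    for i, cell in enumerate(cells):
        for name in ts_names:
            ts[name][i] = cell["series"][name]
        for name in single_names:
            singles[name][i] = cell["singles"][name]
        sync = cell["sync"]
        states[i] = sync.states
        ip[i], ma[i], valid[i] = sync.ip_index, sync.ma_index, sync.valid

    meta = pd.DataFrame(meta_rows, columns=list(META_KEYS) + [
        "cell_id", "pair", "daughter", "track_id"])
    project = Project(ts=ts, singles=singles, meta=meta, states=states,
                      ip=ip, ma=ma, valid=valid, n_before=cfg.n_before,
                      n_after=cfg.n_after, pixel_size=movie.pixel_size,
                      sampling_interval=movie.sampling_interval,
                      config=cfg.as_dict())
    add_derived_features(project)
    return project


def add_derived_features(project: Project,
                         normalize=("mean_int", "area"),
                         slope_features=("area",),
                         slope_window: int = 5) -> Project:
    """Attach normalized series, recovery and slope features in place.

    Derived series enter the registry under a ``derived/`` prefix; single
    features gain per-feature interphase means (used for feature-range
    selections) and post-division recovery slopes.
    """
    from .sync import SyncStates

    n, t_win = project.n_cells, project.window_length
    syncs = [SyncStates(states=project.states[i], ip_index=int(project.ip[i]),
                        ma_index=int(project.ma[i]), valid=bool(project.valid[i]))
             for i in range(n)]
    for name in normalize:
        if name not in project.ts:
            continue
        out = np.full((n, t_win), np.nan)
        for i, sync in enumerate(syncs):
            out[i] = derive.normalize_to_event(project.ts[name][i], sync,
                                               "interphase_mean")
        project.ts[f"derived/{name}_norm"] = out
    recovery = np.full((n, t_win), np.nan)
    for i, sync in enumerate(syncs):
        feats = {k: project.ts[k][i] for k in derive.RECOVERY_FEATURES
                 if k in project.ts}
        if sync.valid and len(feats) == len(derive.RECOVERY_FEATURES):
            recovery[i] = derive.recovery_percentage(feats, sync)
    project.ts["derived/recovery"] = recovery
    for name in project.feature_names:
        if name.startswith("derived/"):
            continue
        mus = np.full(n, np.nan)
        for i, sync in enumerate(syncs):
            if sync.valid:
                vals = project.ts[name][i][sync.states == 1]
                if vals.size:
                    mus[i] = np.nanmean(vals)
        project.singles[f"{name}_interphase_mean"] = mus
    for name in slope_features:
        if name not in project.ts:
            continue
        slopes = np.full(n, np.nan)
        for i, sync in enumerate(syncs):
            if sync.valid:
                slopes[i] = derive.regression_slope(
                    project.ts[name][i], sync.ma_index, slope_window,
                    sampling_interval=project.sampling_interval)
        project.singles[f"{name}_recovery_slope_per_min"] = slopes
    return project
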