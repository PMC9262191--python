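import numpy as np
import pandas as pd
import pytest

from mitotrack import SimParams, generate_movie, run_pipeline
from mitotrack.detect import detect_movie
from mitotrack.io import META_KEYS, Project

#: small movie exercising every stage at low cost
SMALL_PARAMS = SimParams(image_size=(340, 340), n_frames=100, n_cells=5,
                         n_divisions=2, division_schedule=[(1, 36), (2, 34)],
                         seed=7)

#: the default study conditions (20 cells, 5 divisions, 120 frames)
DEFAULT_PARAMS = SimParams(seed=1)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_sim():
    return generate_movie(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_detections(small_sim):
    movie, _ = small_sim
    return detect_movie(movie.chromatin)


@pytest.fixture(scope="session")
def small_project(small_sim):
    movie, _ = small_sim
    return run_pipeline(movie)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic study conditions.

    Detection runs once; tracking, extraction and project assembly reuse it.
    Returns (params, movie, truth, graph, pairs, project).
    """
    from mitotrack.pipeline import PipelineConfig, build_project
    from mitotrack.track import extract_mitotic_trajectories, track_movie

    movie, truth = generate_movie(DEFAULT_PARAMS)
    cfg = PipelineConfig().resolve(movie)
    detections = detect_movie(movie.chromatin, cfg.sigma_range,
                              cfg.threshold_rel, cfg.n_scales)
    graph = track_movie(detections, cutoff=cfg.cutoff,
                        fallback_cutoff=cfg.fallback_cutoff)
    pairs = extract_mitotic_trajectories(graph, cfg.n_before, cfg.n_after)
    project = build_project(movie, pairs, cfg)
    return DEFAULT_PARAMS, movie, truth, graph, pairs, project


def make_project(n_cells=4, n_before=3, n_after=5,
                 treatments=("Scrambled",), seed=0) -> Project:
    """A small in-memory project with valid anchors, for io/report tests."""
    rng = np.random.default_rng(seed)
    t = n_before + n_after
    ts = {"f1": rng.normal(10.0, 1.0, (n_cells, t)),
          "f2": rng.normal(5.0, 0.5, (n_cells, t))}
    singles = {"s1": rng.normal(0.0, 1.0, n_cells)}
    meta = pd.DataFrame({
        **{k: ["x"] * n_cells for k in META_KEYS},
        "cell_id": [f"c{i}" for i in range(n_cells)],
    })
    meta["treatment"] = [treatments[i % len(treatments)]
                         for i in range(n_cells)]
    states = np.empty((n_cells, t), np.int8)
    ip, ma = 2, n_before + 1
    states[:, :ip] = 1
    states[:, ip:ma] = 2
    states[:, ma:] = 3
    return Project(ts=ts, singles=singles, meta=meta, states=states,
                   ip=np.full(n_cells, ip), ma=np.full(n_cells, ma),
                   valid=np.ones(n_cells, bool), n_before=n_before,
                   n_after=n_after)
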