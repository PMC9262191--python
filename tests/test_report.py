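"""Selection, aligned axis, fold-change ranking, statistics and plots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotrack.report import (AlignedTimeAxis, adjust_p_values,
                              aligned_matrix, fold_change_report,
                              fold_change_table, run_single_feature_tests,
                              run_timeseries_anova, select_cells)
from .conftest import make_project


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_metadata_equality_selection():
    project = make_project(n_cells=12, treatments=("Scrambled", "PP2A"))
    sel = select_cells(project, meta_equals={"treatment": "Scrambled"})
    assert len(sel) == 6
    assert set(project.meta.treatment.iloc[sel.cell_ids]) == {"Scrambled"}


def test_conjunction_equals_set_intersection():
    project = make_project(n_cells=20, treatments=("Scrambled", "PP2A"),
                           seed=3)
    lo, hi = -0.5, 0.8
    by_meta = select_cells(project, meta_equals={"treatment": "PP2A"})
    by_range = select_cells(project, single_ranges={"s1": (lo, hi)})
    both = select_cells(project, meta_equals={"treatment": "PP2A"},
                        single_ranges={"s1": (lo, hi)})
    assert set(both.cell_ids) == set(by_meta.cell_ids) & set(by_range.cell_ids)


def test_empty_predicate_selects_all():
    project = make_project(n_cells=7)
    assert len(select_cells(project)) == 7


def test_unknown_keys_listed():
    project = make_project()
    with pytest.raises(KeyError, match="treatment"):
        select_cells(project, meta_equals={"nope": "x"})
    with pytest.raises(KeyError, match="s1"):
        select_cells(project, single_ranges={"nope": (0, 1)})


def test_empty_selection_warns():
    project = make_project()
    with pytest.warns(UserWarning, match="zero cells"):
        sel = select_cells(project, meta_equals={"treatment": "missing"})
    assert len(sel) == 0


# ---------------------------------------------------------------------------
# aligned axis
# ---------------------------------------------------------------------------

@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=2, max_value=60),
       st.integers(min_value=1, max_value=30),
       st.integers(min_value=1, max_value=30))
def test_axis_mapping_monotone_and_anchor_preserving(t_total, ip_off, ma_off):
    ip = min(ip_off, t_total - 2)
    ma = min(ip + ma_off, t_total)
    if not 0 < ip < ma <= t_total:
        return
    axis = AlignedTimeAxis(n_pre=10, n_mid=8, n_post=12)
    pos = axis.positions(ip, ma, t_total)
    assert np.all(np.diff(pos) > 0)
    assert pos[ip] == axis.ip_position
    if ma < t_total:
        assert pos[ma] == axis.ma_position


def test_axis_resample_preserves_constants():
    axis = AlignedTimeAxis(n_pre=5, n_mid=6, n_post=7)
    out = axis.resample(np.full(30, 3.3), ip=10, ma=20)
    covered = np.isfinite(out)
    assert np.allclose(out[covered], 3.3)


def test_aligned_heatmap_rows_one_per_cell():
    project = make_project(n_cells=5)
    axis = AlignedTimeAxis.for_project(project)
    mat = aligned_matrix(project, "f1", np.arange(5), axis)
    assert mat.shape == (5, axis.length)


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def test_constant_feature_folds_are_unity():
    project = make_project(n_cells=4)
    project.ts["const"] = np.full((4, project.window_length), 5.0)
    table = fold_change_table(project).set_index("feature")
    assert table.loc["const"].fold_ip == pytest.approx(1.0)
    assert table.loc["const"].fold_ma == pytest.approx(1.0)


def test_table_covers_whole_feature_registry():
    project = make_project(n_cells=4)
    table = fold_change_table(project)
    assert sorted(table.feature) == project.feature_names


def test_html_report_written(tmp_path):
    project = make_project(n_cells=6)
    table = fold_change_report(project, out_dir=tmp_path, top_plots=2)
    assert (tmp_path / "report.html").exists()
    assert (tmp_path / "fold_change.csv").exists()
    pngs = list(tmp_path.glob("*.png"))
    assert len(pngs) == 2
    assert len(table) == len(project.feature_names)


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------

def test_identical_groups_not_significant():
    vals = np.arange(20, dtype=float)
    out = run_single_feature_tests({"a": vals, "b": vals.copy()}, "t_test")
    assert out.statistic.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out.p_value.iloc[0] == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("test", ["t_test", "anova", "wilcoxon",
                                  "kruskal_wallis"])
def test_separated_groups_highly_significant(test):
    rng = np.random.default_rng(19)
    groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(5, 1, 50)}
    out = run_single_feature_tests(groups, test)
    assert out.p_value.iloc[0] < 1e-6
    assert out.n_a.iloc[0] == 50 and out.n_b.iloc[0] == 50


def test_two_sample_tests_reject_three_groups():
    groups = {k: np.arange(5, dtype=float) for k in "abc"}
    with pytest.raises(ValueError, match="exactly 2"):
        run_single_feature_tests(groups, "t_test")


def test_small_group_excluded_with_warning():
    groups = {"a": np.arange(10, dtype=float),
              "b": np.arange(10, dtype=float) + 3,
              "tiny": np.array([1.0])}
    with pytest.warns(UserWarning, match="tiny"):
        out = run_single_feature_tests(groups, "anova")
    assert "n_tiny" not in out.columns


def test_bh_adjustment_column_added():
    table = pd.DataFrame({"p_value": [0.01, 0.02, 0.5]})
    out = adjust_p_values(table)
    assert "p_value_bh" in out.columns
    assert np.all(out.p_value_bh >= out.p_value - 1e-15)


def _anova_groups(offset, seed=0, n_cells=8, t_total=30):
    rng = np.random.default_rng(seed)
    base = np.sin(np.linspace(0, 2, t_total)) * 2.0 + 10.0
    out = {}
    for g, off in (("A", 0.0), ("B", offset)):
        cells = []
        for _ in range(n_cells):
            series = base + off + rng.normal(0, 0.3, t_total)
            cells.append((series, 8, 20))
        out[g] = cells
    return out


def test_identical_groups_anova_not_significant():
    table = run_timeseries_anova(_anova_groups(0.0, seed=2))
    assert table.loc["treatment", "PR(>F)"] > 0.05


def test_offset_group_loads_on_treatment_not_interaction():
    table = run_timeseries_anova(_anova_groups(5.0, seed=3))
    assert table.loc["treatment", "PR(>F)"] < 1e-6
    assert table.loc["interaction", "PR(>F)"] > 0.05


def test_single_time_point_degenerates_with_clear_error():
    with pytest.raises(ValueError, match="single time point|time bins"):
        run_timeseries_anova(_anova_groups(1.0), n_time_bins=1)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def test_render_plot_kinds(tmp_path):
    from mitotrack.plotting import render_plot

    rng = np.random.default_rng(21)
    mat = rng.normal(0, 1, (6, 40))
    anchors = (10, 25)
    for kind in ("heatmap", "mean_sd", "combined_lines"):
        path = render_plot(kind, {"grp": mat}, tmp_path / f"{kind}.png",
                           anchors=anchors)
        assert path.exists() and path.stat().st_size > 0
    for kind in ("violin", "box", "histogram"):
        path = render_plot(kind, {"a": rng.normal(0, 1, 30),
                                  "b": rng.normal(1, 1, 30)},
                           tmp_path / f"{kind}.png")
        assert path.exists()


def test_duplicated_cell_has_zero_sd_band():
    # the mean +- sd band of a duplicated single cell has zero width
    row = np.sin(np.linspace(0, 3, 25))
    mat = np.vstack([row, row])
    assert np.allclose(np.nanstd(mat, axis=0), 0.0)


def test_temporal_plot_requires_anchors(tmp_path):
    from mitotrack.plotting import render_plot

    with pytest.raises(ValueError, match="synchronized"):
        render_plot("heatmap", {"g": np.zeros((2, 10))}, tmp_path / "x.png")


def test_subplot_grouping_one_axes_per_experiment(tmp_path):
    from mitotrack.plotting import render_plot

    rng = np.random.default_rng(22)
    data = {"exp1": rng.normal(0, 1, (3, 20)),
            "exp2": rng.normal(0, 1, (4, 20))}
    path = render_plot("mean_sd", data, tmp_path / "sub.png",
                       anchors=(5, 12), mode="subplots")
    assert path.exists()
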