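"""Cell selection, grouped statistics, feature ranking and report export.

Selections combine metadata equality predicates (microscope, treatment,
experiment, ...) with ranges on per-cell single features; combining
predicates intersects them.  The fold-change report ranks every feature by
the n-fold change from the interphase average to the average of the first
``window`` prophase frames and the first ``window`` anaphase frames, and
can be rendered as a static HTML page with PNG figures.  Statistical
comparisons of single features across groups cover the two-sample t-test,
one-way ANOVA, the Wilcoxon rank-sum and Kruskal-Wallis tests, plus a
two-way (treatment x time) ANOVA on aligned time series; raw p-values are
reported side by side with Benjamini-Hochberg adjusted ones.
"""

from __future__ import annotations

import html
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Project

SINGLE_FEATURE_TESTS = ("t_test", "anova", "wilcoxon", "kruskal_wallis")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    cell_ids: np.ndarray
    description: str = ""

    def __len__(self) -> int:
        return len(self.cell_ids)


def select_cells(project: Project,
                 meta_equals: dict[str, object] | None = None,
                 single_ranges: dict[str, tuple[float, float]] | None = None,
                 valid_only: bool = False) -> Selection:
    """Resolve a predicate to a deterministic cell-id list.

    ``meta_equals`` maps metadata columns to a value or set of values;
    ``single_ranges`` maps single-feature names to inclusive ``(lo, hi)``
    ranges.  Predicates intersect.  Unknown keys raise, listing the valid
    ones; an empty result is allowed (with a warning).
    """
    keep = np.ones(project.n_cells, dtype=bool)
    parts = []
    for key, value in (meta_equals or {}).items():
        if key not in project.meta.columns:
            raise KeyError(f"unknown metadata key '{key}'; valid keys: "
                           f"{sorted(project.meta.columns)}")
        values = value if isinstance(value, (set, list, tuple)) else {value}
        keep &= project.meta[key].isin({str(v) for v in values}).to_numpy()
        parts.append(f"{key} in {sorted(str(v) for v in values)}")
    for name, (lo, hi) in (single_ranges or {}).items():
        if name not in project.singles:
            raise KeyError(f"unknown single feature '{name}'; valid names: "
                           f"{project.single_names}")
        vals = project.singles[name]
        keep &= np.isfinite(vals) & (vals >= lo) & (vals <= hi)
        parts.append(f"{name} in [{lo}, {hi}]")
    if valid_only:
        keep &= project.valid
        parts.append("valid")
    ids = np.flatnonzero(keep)
    if ids.size == 0:
        warnings.warn("selection resolved to zero cells", stacklevel=2)
    return Selection(cell_ids=ids, description=" and ".join(parts) or "all cells")


# ---------------------------------------------------------------------------
# aligned time axis
# ---------------------------------------------------------------------------

@dataclass
class AlignedTimeAxis:
    """Common three-segment plotting axis for variable-length trajectories.

    The axis concatenates an interphase block of ``n_pre`` frames ending at
    the IP anchor, a mitotic block of ``n_mid`` positions onto which each
    cell's variable-length [IP, MA) segment is stretched uniformly, and a
    post-MA block of ``n_post`` frames.  IP and MA map to the same axis
    positions for every cell and the mapping is monotone.
    """

    n_pre: int
    n_mid: int
    n_post: int

    @property
    def length(self) -> int:
        return self.n_pre + self.n_mid + self.n_post

    @property
    def ip_position(self) -> int:
        return self.n_pre

    @property
    def ma_position(self) -> int:
        return self.n_pre + self.n_mid

    def positions(self, ip: int, ma: int, n_frames: int) -> np.ndarray:
        """Axis position of every original frame (monotone, anchors fixed)."""
        if not 0 < ip < ma <= n_frames:
            raise ValueError("need 0 < ip < ma <= n_frames")
        t = np.arange(n_frames, dtype=float)
        pos = np.empty(n_frames, dtype=float)
        pre = t < ip
        mid = (t >= ip) & (t < ma)
        post = t >= ma
        pos[pre] = self.n_pre - (ip - t[pre])
        pos[mid] = self.n_pre + (t[mid] - ip) * self.n_mid / (ma - ip)
        pos[post] = self.n_pre + self.n_mid + (t[post] - ma)
        return pos

    def resample(self, series: np.ndarray, ip: int, ma: int) -> np.ndarray:
        """Map one cell's series onto the axis (NaN where uncovered)."""
        x = np.asarray(series, float)
        out = np.full(self.length, np.nan)
        pre = x[max(0, ip - self.n_pre):ip]
        out[self.n_pre - len(pre):self.n_pre] = pre
        src = np.linspace(ip, ma, self.n_mid, endpoint=False)
        frames = np.arange(len(x), dtype=float)
        out[self.n_pre:self.n_pre + self.n_mid] = np.interp(src, frames, x)
        post = x[ma:ma + self.n_post]
        out[self.n_pre + self.n_mid:self.n_pre + self.n_mid + len(post)] = post
        return out

    @classmethod
    def for_project(cls, project: Project, cell_ids=None,
                    n_mid: int | None = None) -> "AlignedTimeAxis":
        ids = (np.flatnonzero(project.valid) if cell_ids is None
               else np.asarray(cell_ids))
        ids = ids[project.valid[ids]]
        if ids.size == 0:
            raise ValueError("no valid synchronized cells to align")
        ip, ma = project.ip[ids], project.ma[ids]
        n_pre = int(ip.max())
        n_post = int((project.window_length - ma).max())
        if n_mid is None:
            n_mid = max(2, int(round(float(np.median(ma - ip)))))
        return cls(n_pre=n_pre, n_mid=n_mid, n_post=n_post)


def aligned_matrix(project: Project, feature: str, cell_ids,
                   axis: AlignedTimeAxis) -> np.ndarray:
    """Stack one feature of the selected valid cells onto the common axis."""
    ids = np.asarray(cell_ids, int)
    ids = ids[project.valid[ids]]
    rows = [axis.resample(project.ts[feature][i], int(project.ip[i]),
                          int(project.ma[i])) for i in ids]
    return np.array(rows) if rows else np.empty((0, axis.length))


# ---------------------------------------------------------------------------
# fold-change feature ranking
# ---------------------------------------------------------------------------

def fold_change_table(project: Project, selection: Selection | None = None,
                      window: int = 2) -> pd.DataFrame:
    """Per-feature fold changes from interphase to prophase and anaphase.

    For every feature and valid cell, the interphase mean is compared with
    the mean over the first ``window`` state-2 frames (fold_ip) and the
    first ``window`` state-3 frames (fold_ma); cell-level folds are
    averaged.  The table adds min/max/mean/std/median of the pooled series
    values and is ranked by the larger absolute log fold change.
    """
    ids = (selection.cell_ids if selection is not None
           else np.arange(project.n_cells))
    ids = ids[project.valid[ids]]
    if ids.size == 0:
        raise ValueError("fold-change report needs synchronized cells")
    rows = []
    for name in project.feature_names:
        arr = project.ts[name]
        folds_ip, folds_ma, pooled = [], [], []
        for i in ids:
            x = arr[i]
            states = project.states[i]
            ref = x[states == 1]
            ref = ref[np.isfinite(ref)]
            mu = float(ref.mean()) if ref.size else np.nan
            pooled.append(x)
            if not np.isfinite(mu) or mu == 0:
                continue
            for target, sink in ((2, folds_ip), (3, folds_ma)):
                idx = np.flatnonzero(states == target)[:window]
                vals = x[idx]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    sink.append(float(vals.mean()) / mu)
        pooled = np.concatenate(pooled)
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            pooled = np.array([np.nan])
        fold_ip = float(np.mean(folds_ip)) if folds_ip else np.nan
        fold_ma = float(np.mean(folds_ma)) if folds_ma else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.abs(np.log(np.array([fold_ip, fold_ma], dtype=float)))
        logs = logs[np.isfinite(logs)]
        rank_key = float(logs.max()) if logs.size else np.nan
        rows.append({
            "feature": name, "fold_ip": fold_ip, "fold_ma": fold_ma,
            "min": float(np.min(pooled)), "max": float(np.max(pooled)),
            "mean": float(np.mean(pooled)), "std": float(np.std(pooled)),
            "median": float(np.median(pooled)),
            "abs_log_fold": rank_key,
        })
    table = pd.DataFrame(rows)
    return table.sort_values("abs_log_fold", ascending=False,
                             na_position="last").reset_index(drop=True)


def fold_change_report(project: Project, selection: Selection | None = None,
                       window: int = 2, out_dir=None,
                       top_plots: int = 8) -> pd.DataFrame:
    """Ranked fold-change table, optionally rendered as a static HTML page.

    The HTML report embeds the table and aligned mean +- sd line plots of
    the ``top_plots`` highest-ranked features (PNG, no scripting).
    """
    table = fold_change_table(project, selection, window)
    if out_dir is None:
        return table
    from pathlib import Path

    from .plotting import render_plot

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "fold_change.csv", index=False)
    ids = (selection.cell_ids if selection is not None
           else np.arange(project.n_cells))
    axis = AlignedTimeAxis.for_project(project, ids)
    figures = []
    for name in table["feature"].head(top_plots):
        mat = aligned_matrix(project, name, ids, axis)
        fig_path = out / f"feature_{name.replace('/', '_')}.png"
        render_plot("mean_sd", {"selection": mat}, fig_path,
                    anchors=(axis.ip_position, axis.ma_position), title=name)
        figures.append((name, fig_path.name))
    rows_html = table.to_html(index=False, float_format=lambda v: f"{v:.4g}",
                              border=0)
    imgs = "\n".join(
        f"<h3>{html.escape(str(name))}</h3><img src='{fname}' width='640'/>"
        for name, fname in figures)
    page = ("<html><head><title>Feature fold-change report</title></head>"
            f"<body><h1>Feature fold-change report</h1>{rows_html}"
            f"{imgs}</body></html>")
    (out / "report.html").write_text(page)
    return table


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------

def run_single_feature_tests(values_by_group: dict[str, np.ndarray],
                             test: str) -> pd.DataFrame:
    """Compare a single feature across groups; spreadsheet-ready table.

    ``t_test`` and ``wilcoxon`` (rank-sum) require exactly two groups;
    ``anova`` and ``kruskal_wallis`` take two or more.  Groups with fewer
    than two observations are excluded with a warning.  Benjamini-Hochberg
    adjustment is applied when several tests are tabulated together via
    :func:`adjust_p_values`.
    """
    if test not in SINGLE_FEATURE_TESTS:
        raise ValueError(f"unknown test '{test}'; use one of "
                         f"{SINGLE_FEATURE_TESTS}")
    groups = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            warnings.warn(f"group '{name}' has fewer than 2 observations "
                          "and is excluded", stacklevel=2)
            continue
        groups[name] = arr
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    names = sorted(groups)
    samples = [groups[n] for n in names]
    if test in ("t_test", "wilcoxon") and len(samples) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(samples)}")
    if test == "t_test":
        stat, p = sps.ttest_ind(*samples)
    elif test == "wilcoxon":
        stat, p = sps.ranksums(*samples)
    elif test == "anova":
        stat, p = sps.f_oneway(*samples)
    else:
        stat, p = sps.kruskal(*samples)
    row = {"test": test, "groups": ", ".join(names),
           "statistic": float(stat), "p_value": float(p)}
    for name in names:
        row[f"n_{name}"] = len(groups[name])
    return pd.DataFrame([row])


def adjust_p_values(table: pd.DataFrame,
                    column: str = "p_value") -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted column next to the raw one."""
    from statsmodels.stats.multitest import multipletests

    out = table.copy()
    p = out[column].to_numpy(float)
    good = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if good.any():
        adj[good] = multipletests(p[good], method="fdr_bh")[1]
    out[column + "_bh"] = adj
    return out


def run_timeseries_anova(series_by_group: dict[str, list[tuple[np.ndarray, int, int]]],
                         n_time_bins: int = 10) -> pd.DataFrame:
    """Two-way (treatment x time) ANOVA on aligned time series.

    Each group maps to a list of ``(series, ip, ma)`` per cell; the
    variable-length [IP, MA) block of every cell is resampled onto
    ``n_time_bins`` bins so that corresponding mitotic stages are compared.
    Returns the ANOVA table with factors treatment, time and interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(series_by_group) < 2:
        raise ValueError("two-way ANOVA needs at least 2 groups")
    if n_time_bins < 2:
        raise ValueError("need at least 2 time bins; a single time point "
                         "cannot support a treatment x time ANOVA")
    records = []
    for group, cells in series_by_group.items():
        for series, ip, ma in cells:
            x = np.asarray(series, float)
            if not 0 < ip < ma <= len(x):
                raise ValueError("invalid anchors for a cell in group "
                                 f"'{group}'")
            src = np.linspace(ip, ma, n_time_bins, endpoint=False)
            vals = np.interp(src, np.arange(len(x), dtype=float), x)
            for t, v in enumerate(vals):
                records.append({"treatment": group, "time": t, "value": v})
    df = pd.DataFrame(records)
    counts = df.groupby(["treatment", "time"]).size()
    if (counts < 1).any():  # pragma: no cover - resampling fills all bins
        missing = counts[counts < 1].index.tolist()
        raise ValueError(f"empty (group, time) cells: {missing}")
    model = smf.ols("value ~ C(treatment) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={
        "C(treatment)": "treatment", "C(time)": "time",
        "C(treatment):C(time)": "interaction"})
    return table
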