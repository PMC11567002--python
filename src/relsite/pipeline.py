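"""End-to-end orchestration: movies to spatial statistics, traces to kinetics.

``run_release_mapping`` chains detection → localization → merging →
ROI assignment → release-site clustering → AZ geometry and produces a
per-synapse summary table, pooled distance distributions and a
per-stage count report. ``run_retrieval_analysis`` fits endocytic time
constants on a designated control group and quantifies the fractional
retrieval block of every group against the control 2τ.
``compare_groups`` delegates the statistics: Kolmogorov-Smirnov for
pooled event-level distributions, Mann-Whitney U for per-synapse
metrics of two groups, Kruskal-Wallis for three or more.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import azgeom, detect, io, kinetics, sites
from .detect import DetectionConfig
from .kinetics import NonDecayingError, Trace
from .synth import Movie

SUMMARY_COLUMNS = [
    "synapse_id",
    "group",
    "n_events",
    "release_pr",
    "n_sites",
    "az_area_nm2",
    "az_degenerate",
    "mean_dist_to_center_nm",
    "mean_consecutive_dist_nm",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a release-mapping run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    clustering_diameter_nm: float = sites.DEFAULT_CLUSTERING_DIAMETER_NM
    merge_gap_frames: int = 1
    merge_radius_nm: float = 100.0
    bin_width_nm: float = azgeom.DEFAULT_BIN_WIDTH_NM
    pooling: str = "event"  # "event" pools distances across synapses; "synapse" averages within first

    def __post_init__(self) -> None:
        if self.pooling not in ("event", "synapse"):
            raise ValueError("pooling must be 'event' or 'synapse'")
        if self.clustering_diameter_nm <= 0:
            raise ValueError("clustering_diameter_nm must be positive")


@dataclass
class MovieDataset:
    """One movie with its ROIs and experimental group label."""

    name: str
    group: str
    movie: Movie | str
    rois: io.RoiSet | str


@dataclass
class ReleaseMappingResult:
    summary: pd.DataFrame
    events: pd.DataFrame
    site_table: pd.DataFrame
    distances_to_center: dict  # group -> pooled nm distances
    consecutive_distances: dict
    report: dict


def _config_hash(cfg: RunConfig, datasets) -> str:
    h = hashlib.sha256()
    h.update(repr(cfg).encode())
    for ds in datasets:
        h.update(ds.name.encode())
        h.update(ds.group.encode())
        movie = ds.movie
        if isinstance(movie, Movie):
            h.update(np.ascontiguousarray(movie.data).tobytes())
        else:
            h.update(str(movie).encode())
    return h.hexdigest()


def run_release_mapping(cfg: RunConfig, datasets: list[MovieDataset], protocol) -> ReleaseMappingResult:
    """Run the full mapping chain over a list of movie datasets.

    Deterministic given the same config and inputs (no randomness after
    data generation). The report records per-stage counts so every
    summary row is traceable: candidates found, fits kept and discarded
    by reason, detections merged, events assigned per synapse.
    """
    all_events = []
    report = {"stages": {}, "config_hash": _config_hash(cfg, datasets)}
    for ds in datasets:
        movie = ds.movie if isinstance(ds.movie, Movie) else io.read_movie(ds.movie)
        rois = ds.rois if isinstance(ds.rois, io.RoiSet) else io.read_rois(ds.rois)
        cands = detect.detect_candidates(movie, cfg.detection)
        fitted, discards = detect.fit_spots(movie, cands, cfg.detection)
        merged = detect.merge_consecutive_detections(
            fitted, max_gap_frames=cfg.merge_gap_frames, radius_nm=cfg.merge_radius_nm
        )
        assigned = detect.assign_to_synapses(merged, rois)
        assigned.insert(0, "dataset", ds.name)
        assigned.insert(1, "group", ds.group)
        all_events.append(assigned)
        report["stages"][ds.name] = {
            "n_candidates": int(len(cands)),
            "n_fitted": int(len(fitted)),
            "discards": discards,
            "n_merged_events": int(len(merged)),
            "n_assigned": int(assigned["synapse_id"].notna().sum()),
            "n_unassigned": int(assigned["synapse_id"].isna().sum()),
        }
        if len(rois) == 0:
            report["stages"][ds.name]["warning"] = "empty ROI set"

    events = (
        pd.concat(all_events, ignore_index=True)
        if all_events
        else pd.DataFrame(columns=["dataset", "group", "synapse_id"])
    )
    assigned = events[events["synapse_id"].notna()]

    summary_rows = []
    site_tables = []
    d2c: dict[str, list] = {}
    cons: dict[str, list] = {}
    for (ds_name, group, sid), grp in assigned.groupby(["dataset", "group", "synapse_id"], sort=True):
        pts = grp[["x_nm", "y_nm"]].to_numpy()
        sset = sites.cluster_events(pts, cfg.clustering_diameter_nm, synapse_id=f"{ds_name}/{sid}")
        site_tables.append(sites.site_table(sset))
        geom = azgeom.az_hull(pts, synapse_id=f"{ds_name}/{sid}")
        dist, _ = azgeom.distances_to_center(pts, geom, cfg.bin_width_nm)
        if len(grp) >= 2:
            cdist, _ = azgeom.consecutive_event_distances(grp, cfg.bin_width_nm)
        else:
            cdist = np.empty(0)
        pr = kinetics.release_probability(len(grp), protocol)
        summary_rows.append(
            (
                f"{ds_name}/{sid}",
                group,
                len(grp),
                pr,
                sset.n_sites,
                geom.area,
                geom.degenerate,
                float(dist.mean()),
                float(cdist.mean()) if cdist.size else np.nan,
            )
        )
        if cfg.pooling == "event":
            d2c.setdefault(group, []).append(dist)
            cons.setdefault(group, []).append(cdist)
        else:
            d2c.setdefault(group, []).append(np.array([dist.mean()]))
            cons.setdefault(group, []).append(np.array([cdist.mean()]) if cdist.size else np.empty(0))

    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    site_table = (
        pd.concat(site_tables, ignore_index=True)
        if site_tables
        else pd.DataFrame(columns=sites.SITE_TABLE_COLUMNS)
    )
    d2c_pooled = {g: np.concatenate(v) if v else np.empty(0) for g, v in d2c.items()}
    cons_pooled = {g: np.concatenate(v) if v else np.empty(0) for g, v in cons.items()}
    return ReleaseMappingResult(summary, events, site_table, d2c_pooled, cons_pooled, report)


def run_retrieval_analysis(
    traces: list[Trace],
    groups: list[str],
    control_group: str,
    anchored: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Endocytic τ fits plus fractional retrieval block for every trace.

    The control time constant is the mean τ over the control group's
    converged fits; that single value (doubled) sets the read-out time
    for every group — the treated groups' own τ is never substituted.
    Non-converged and non-decaying fits are excluded from the control
    mean and flagged in the output table.
    """
    if len(traces) != len(groups):
        raise ValueError("one group label per trace is required")
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present among group labels")

    rows = []
    for k, (tr, grp) in enumerate(zip(traces, groups)):
        dff = kinetics.normalize_dff(tr)
        try:
            fit = kinetics.fit_endocytic_tau(dff, tr.stimulus, tr.frame_interval_s, anchored=anchored)
            tau, conv, df_max = fit.tau_s, fit.converged, fit.delta_f_max
        except NonDecayingError:
            tau, conv, df_max = np.nan, False, np.nan
        rows.append(
            {
                "roi_id": tr.roi_id if tr.roi_id is not None else f"roi{k}",
                "group": grp,
                "tau_s": tau,
                "delta_f_max": df_max,
                "converged": conv,
            }
        )
    fits = pd.DataFrame(rows)
    ctrl = fits[(fits["group"] == control_group) & fits["converged"]]
    if ctrl.empty:
        raise ValueError("no converged endocytic fits in the control group")
    control_tau = float(ctrl["tau_s"].mean())

    blocks = []
    for tr in traces:
        dff = kinetics.normalize_dff(tr)
        try:
            blocks.append(
                kinetics.fractional_retrieval_block(dff, control_tau, tr.stimulus, tr.frame_interval_s)
            )
        except ValueError:
            blocks.append(np.nan)
    fits["fractional_retrieval_block"] = blocks
    return fits, control_tau


def grubbs_outliers(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs' test; returns a boolean outlier mask.

    The classic single-outlier test applied repeatedly: the most
    extreme point is removed while its G statistic exceeds the critical
    value from the t distribution. Off by default in the pipeline; when
    enabled, removed rows are logged in the report.
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    idx = np.arange(x.size)
    while idx.size > 2:
        sub = x[idx]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(sub - mean) / sd
        imax = int(np.argmax(g))
        n = idx.size
        t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        if g[imax] > g_crit:
            mask[idx[imax]] = True
            idx = np.delete(idx, imax)
        else:
            break
    return mask


def compare_groups(
    df: pd.DataFrame,
    value: str,
    group: str,
    level: str = "synapse",
    remove_outliers: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-or-more-group comparison of a metric column.

    ``level='event'`` uses the two-sample Kolmogorov-Smirnov test on the
    pooled distributions; ``level='synapse'`` uses Mann-Whitney U for
    two groups and Kruskal-Wallis for three or more. Effect sizes
    (difference of means and medians) are reported alongside p-values.
    Optional Grubbs' outlier removal is applied per group before
    testing.
    """
    if level not in ("event", "synapse"):
        raise ValueError("level must be 'event' or 'synapse'")
    data = df[[group, value]].dropna()
    labels = sorted(data[group].unique())
    if len(labels) < 2:
        raise ValueError("compare_groups needs at least two groups")
    samples = []
    n_removed = 0
    for lab in labels:
        x = data.loc[data[group] == lab, value].to_numpy(dtype=float)
        if remove_outliers and x.size > 2:
            out = grubbs_outliers(x, alpha)
            n_removed += int(out.sum())
            x = x[~out]
        samples.append(x)

    if len(labels) == 2:
        a, b = samples
        if level == "event":
            res = stats.ks_2samp(a, b)
            test = "ks_2samp"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mannwhitneyu"
        stat, p = float(res.statistic), float(res.pvalue)
        eff_mean = float(b.mean() - a.mean())
        eff_median = float(np.median(b) - np.median(a))
    else:
        res = stats.kruskal(*samples)
        test = "kruskal"
        stat, p = float(res.statistic), float(res.pvalue)
        eff_mean = float(max(s.mean() for s in samples) - min(s.mean() for s in samples))
        eff_median = float(max(np.median(s) for s in samples) - min(np.median(s) for s in samples))

    return pd.DataFrame(
        [
            {
                "metric": value,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "mean_diff": eff_mean,
                "median_diff": eff_median,
                "groups": "|".join(str(l) for l in labels),
                "n": "|".join(str(s.size) for s in samples),
                "n_outliers_removed": n_removed,
            }
        ]
    )


def write_run_outputs(outdir, result: ReleaseMappingResult) -> None:
    """Write the mapping result as CSV tables plus a JSON run manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(outdir / "synapse_summary.csv", result.summary)
    io.write_table(outdir / "events.csv", result.events)
    io.write_table(outdir / "sites.csv", result.site_table)
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
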