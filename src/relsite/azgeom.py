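"""Active-zone geometry and spatial statistics of release events.

The functional active zone (AZ) of a bouton is operationalized as the
convex hull of all fusion-event localizations; its centre is the mean
event position (not the hull-polygon centroid, which is exposed as an
alternative). Spatial observables are the per-event distance to the AZ
centre and the distance between temporally consecutive events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import ks_2samp

DEFAULT_BIN_WIDTH_NM = 10.0


@dataclass
class AZGeometry:
    """Convex-hull geometry of one bouton's release events (nm units).

    ``center`` is the arithmetic mean of all event positions.
    ``degenerate`` is True when fewer than 3 non-collinear events
    exist; such AZs have zero area but still define a centre, so they
    are kept for distance statistics and only excluded from area
    summaries.
    """

    synapse_id: str | int | None
    hull_vertices: np.ndarray  # ordered counter-clockwise
    area: float
    center: np.ndarray
    degenerate: bool
    n_events: int


def _polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon (shoelace)."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        return vertices.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def az_hull(events: np.ndarray, synapse_id=None) -> AZGeometry:
    """Convex hull, shoelace area and mean-position centre of an event set.

    Collinear or <3 events give a degenerate AZ with area 0; the hull
    vertices then reduce to the extreme points of the set.
    """
    pts = np.atleast_2d(np.asarray(events, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("events must be an (n, 2) array with n >= 1")
    center = pts.mean(axis=0)
    n = pts.shape[0]
    if n >= 3:
        try:
            hull = ConvexHull(pts)
            vertices = pts[hull.vertices]  # counter-clockwise in 2D
            return AZGeometry(synapse_id, vertices, float(hull.volume), center, False, n)
        except QhullError:
            pass  # collinear
    # degenerate: extremes along the dominant direction
    if n == 1:
        vertices = pts.copy()
    else:
        d = pts - center
        u = d[np.argmax(np.linalg.norm(d, axis=1))]
        proj = d @ u
        vertices = np.array([pts[np.argmin(proj)], pts[np.argmax(proj)]])
    return AZGeometry(synapse_id, vertices, 0.0, center, True, n)


def hull_polygon_centroid(geometry: AZGeometry) -> np.ndarray:
    """Alternative AZ centre: the centroid of the hull polygon itself."""
    if geometry.degenerate:
        return geometry.hull_vertices.mean(axis=0)
    return _polygon_centroid(geometry.hull_vertices)


def _distance_distribution(dist: np.ndarray, bin_width: float) -> pd.DataFrame:
    edges = np.arange(0.0, dist.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(dist, bins=edges)
    frac = counts / dist.size
    return pd.DataFrame(
        {
            "bin_left_nm": edges[:-1],
            "bin_right_nm": edges[1:],
            "count": counts,
            "fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )


def distances_to_center(
    events: np.ndarray,
    geometry: AZGeometry,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-event Euclidean distance to the AZ centre, plus its histogram.

    The histogram is normalized as fraction of total events with a
    cumulative column; bins are ``bin_width`` nm wide starting at 0.
    """
    pts = np.atleast_2d(np.asarray(events, dtype=float))
    dist = np.hypot(pts[:, 0] - geometry.center[0], pts[:, 1] - geometry.center[1])
    return dist, _distance_distribution(dist, bin_width)


def consecutive_event_distances(
    events: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Distances between temporally consecutive events in one synapse.

    ``events`` must carry ``frame, x_nm, y_nm`` columns; rows are
    ordered by frame, ties broken by their existing (detection) order.
    Needs at least two events.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events for consecutive distances")
    ev = events.sort_values("frame", kind="stable")
    x = ev["x_nm"].to_numpy()
    y = ev["y_nm"].to_numpy()
    dist = np.hypot(np.diff(x), np.diff(y))
    return dist, _distance_distribution(dist, bin_width)


def center_shift_summary(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Compare two pooled distance distributions.

    Two-sample Kolmogorov-Smirnov test (delegated to scipy) with simple
    effect summaries: difference of means and of medians (B − A, nm).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = ks_2samp(a, b)
    return {
        "ks_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_diff_nm": float(b.mean() - a.mean()),
        "median_diff_nm": float(np.median(b) - np.median(a)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
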