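"""Fusion-event detection and sub-pixel localization.

Candidate spots are local maxima of band-pass-filtered difference
images (each frame minus a rolling baseline of the preceding frames)
above a robust-SD threshold. Each candidate is then fit by least
squares with a mixture of k integrated 2D Gaussian kernels plus a
constant background; k is chosen by a nested-model F-test up to a cap.
Localization precision is the standard error of the fitted centre,
propagated from the fit's parameter covariance, reported in nm.

Coordinate convention: the origin sits at the centre of pixel (0, 0),
x runs along columns and y along rows; all outputs are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .synth import Movie, _integrated_gaussian_patch

#: Columns of the localization table written by :func:`fit_spots`.
EVENT_TABLE_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "amplitude",
    "background",
    "sigma_psf_nm",
    "precision_nm",
    "n_kernels_in_fit",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of detection and fitting.

    ``threshold`` is in multiples of the robust (MAD-based) SD of the
    filtered difference image. ``bandpass_sigmas_px`` are the two
    Gaussian scales of the difference-of-Gaussians band-pass.
    ``psf_sigma_nm`` is the (fixed) Gaussian PSF width used by the
    fitter. ``alpha`` is the significance level of the nested F-test
    that admits an extra kernel, capped at ``max_kernels`` per window.
    Fits whose centre SE exceeds ``max_precision_nm`` are discarded.
    """

    threshold: float = 4.0
    bandpass_sigmas_px: tuple[float, float] = (1.0, 3.0)
    baseline_frames: int = 3
    fit_window_halfwidth: int = 4
    max_kernels: int = 3
    alpha: float = 0.05
    psf_sigma_nm: float = 110.0
    pixel_size_nm: float = 87.0
    max_precision_nm: float = 100.0
    weighting: str = "poisson"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.fit_window_halfwidth < 1 or 2 * self.fit_window_halfwidth + 1 < 3:
            raise ValueError("fit window must span at least 3 px")
        if self.max_kernels < 1:
            raise ValueError("max_kernels must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.psf_sigma_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("psf_sigma_nm and pixel_size_nm must be positive")
        if self.weighting not in ("poisson", "none"):
            raise ValueError("weighting must be 'poisson' or 'none'")


def _robust_sd(x: np.ndarray, k: float = 3.0, iters: int = 4) -> float:
    """Sigma-clipped SD: the noise scale of an image containing sparse spots.

    Iteratively discards values more than ``k`` SDs from the mean, so a
    few bright spots do not inflate (nor a heavy centre deflate) the
    noise estimate the detection threshold is scaled by.
    """
    x = x.ravel()
    if x.size == 0 or np.ptp(x) == 0:
        return 0.0
    mask = np.ones(x.size, dtype=bool)
    for _ in range(iters):
        sub = x[mask]
        if sub.size < 8:
            break
        m, s = sub.mean(), sub.std()
        if s == 0:
            return 0.0
        new = np.abs(x - m) < k * s
        if new.sum() == mask.sum():
            break
        mask = new
    return float(x[mask].std())


def detect_candidates(movie: Movie, cfg: DetectionConfig) -> pd.DataFrame:
    """Find candidate event pixels per frame.

    For frame t the rolling baseline is the mean of the preceding
    ``cfg.baseline_frames`` frames (frame 0, having no predecessor, is
    compared against itself and yields no candidates). Candidates are
    local maxima of the band-pass-filtered (difference-of-Gaussians)
    difference image that pass three significance checks, each at
    ``threshold`` robust SDs of its own statistic: the matched-filter
    value itself, the raw difference amplitude at the peak pixel, and
    the 3x3 neighbourhood sum. Requiring all three keeps the false-
    positive rate of pure-noise frames far below that of any single
    statistic, because noise rarely exceeds the threshold in all of
    them at once. Returns a DataFrame with ``frame, row, col, value``
    columns; a constant movie yields an empty table.
    """
    s1, s2 = cfg.bandpass_sigmas_px
    records = []
    data = movie.data
    box = np.ones((3, 3))
    for t in range(movie.n_frames):
        t0 = max(0, t - cfg.baseline_frames)
        baseline = data[t0:t].mean(axis=0) if t > 0 else data[t]
        diff = data[t] - baseline
        filt = ndimage.gaussian_filter(diff, s1) - ndimage.gaussian_filter(diff, s2)
        sd_filt = _robust_sd(filt)
        sd_diff = _robust_sd(diff)
        if sd_filt == 0 or sd_diff == 0:
            continue
        neighborhood = ndimage.convolve(diff, box, mode="constant")
        maxima = (
            (filt == ndimage.maximum_filter(filt, size=3))
            & (filt > cfg.threshold * sd_filt)
            & (diff > cfg.threshold * sd_diff)
            & (neighborhood > cfg.threshold * 3.0 * sd_diff)
        )
        rr, cc = np.nonzero(maxima)
        for r, c in zip(rr, cc):
            records.append((t, int(r), int(c), float(filt[r, c])))
    return pd.DataFrame(records, columns=["frame", "row", "col", "value"])


def _mixture_model(params, sigma_px, cols, rows, k):
    """k integrated Gaussians + constant background over a pixel window."""
    model = np.full((rows.size, cols.size), params[-1])
    for i in range(k):
        x, y, amp = params[3 * i : 3 * i + 3]
        model += amp * _integrated_gaussian_patch(x, y, sigma_px, cols, rows)
    return model


def _fit_k_kernels(window, cols, rows, sigma_px, k, inits, weighting="poisson"):
    x0 = []
    lo, hi = [], []
    bg0 = float(np.median(window))
    for (cx, cy) in inits[:k]:
        amp0 = max(window.max() - bg0, 1e-3) * 2 * np.pi * sigma_px**2
        x0 += [cx, cy, amp0]
        lo += [cols[0] - 1.0, rows[0] - 1.0, 1e-9]
        hi += [cols[-1] + 1.0, rows[-1] + 1.0, np.inf]
    x0.append(bg0)
    lo.append(-np.inf)
    hi.append(np.inf)

    if weighting == "poisson":
        # variance-stabilised residuals: photon-count noise scales with
        # the model mean, so unweighted residuals would let the quiet
        # background dominate the fit's noise estimate.
        def resid(p):
            model = _mixture_model(p, sigma_px, cols, rows, k)
            return ((model - window) / np.sqrt(np.clip(model, 1.0, None))).ravel()
    else:
        def resid(p):
            return (_mixture_model(p, sigma_px, cols, rows, k) - window).ravel()

    return least_squares(resid, np.asarray(x0), bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)


def fit_spots(
    movie: Movie,
    candidates: pd.DataFrame,
    cfg: DetectionConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Localize candidates by mixture-model fitting.

    Each candidate seeds a square fit window of half-width
    ``cfg.fit_window_halfwidth`` pixels. Kernels are added one at a
    time (initialised at the largest residual) while a nested-model
    F-test finds the larger model significantly better at ``cfg.alpha``,
    up to ``cfg.max_kernels``. Only the kernel nearest the candidate
    pixel is reported for that candidate, so one candidate yields at
    most one localization.

    Returns the localization table (:data:`EVENT_TABLE_COLUMNS`) and a
    dictionary of discard counts keyed by reason
    (``no_convergence``, ``singular``, ``low_precision``, ``bad_amplitude``).
    """
    sigma_px = cfg.psf_sigma_nm / cfg.pixel_size_nm
    px = cfg.pixel_size_nm
    hw = cfg.fit_window_halfwidth
    n_rows, n_cols = movie.data.shape[1:]
    records = []
    discards = {"no_convergence": 0, "singular": 0, "low_precision": 0, "bad_amplitude": 0}

    for frame, grp in candidates.groupby("frame"):
        img = movie.data[int(frame)]
        for _, cand in grp.iterrows():
            r, c = int(cand["row"]), int(cand["col"])
            r0, r1 = max(0, r - hw), min(n_rows, r + hw + 1)
            c0, c1 = max(0, c - hw), min(n_cols, c + hw + 1)
            window = img[r0:r1, c0:c1].astype(float)
            cols = np.arange(c0, c1, dtype=float)
            rows = np.arange(r0, r1, dtype=float)
            if np.ptp(window) == 0:
                discards["singular"] += 1
                continue

            inits = [(float(c), float(r))]
            sol = _fit_k_kernels(window, cols, rows, sigma_px, 1, inits, cfg.weighting)
            best, best_k = sol, 1
            n_data = window.size
            while best_k < cfg.max_kernels:
                resid_img = window - _mixture_model(best.x, sigma_px, cols, rows, best_k)
                rmax = np.unravel_index(np.argmax(resid_img), resid_img.shape)
                inits = [(best.x[3 * i], best.x[3 * i + 1]) for i in range(best_k)]
                inits.append((cols[rmax[1]], rows[rmax[0]]))
                trial = _fit_k_kernels(window, cols, rows, sigma_px, best_k + 1, inits, cfg.weighting)
                ssr0 = 2 * best.cost
                ssr1 = 2 * trial.cost
                p1 = 3 * (best_k + 1) + 1
                dof = n_data - p1
                if dof <= 0 or ssr1 <= 0:
                    break
                fstat = ((ssr0 - ssr1) / 3.0) / (ssr1 / dof)
                if fstat > 0 and f_dist.sf(fstat, 3, dof) < cfg.alpha:
                    best, best_k = trial, best_k + 1
                else:
                    break

            if not best.success:
                discards["no_convergence"] += 1
                continue
            p = 3 * best_k + 1
            dof = n_data - p
            ssr = 2 * best.cost
            jtj = best.jac.T @ best.jac
            try:
                cov = np.linalg.inv(jtj) * (ssr / max(dof, 1))
            except np.linalg.LinAlgError:
                discards["singular"] += 1
                continue

            # report the kernel nearest the seeding candidate pixel
            centers = np.array([[best.x[3 * i], best.x[3 * i + 1]] for i in range(best_k)])
            ki = int(np.argmin(np.hypot(centers[:, 0] - c, centers[:, 1] - r)))
            x_px, y_px, amp = best.x[3 * ki : 3 * ki + 3]
            var_x = cov[3 * ki, 3 * ki]
            var_y = cov[3 * ki + 1, 3 * ki + 1]
            if var_x < 0 or var_y < 0:
                discards["singular"] += 1
                continue
            precision_nm = float(np.sqrt(0.5 * (var_x + var_y))) * px
            if amp <= 0:
                discards["bad_amplitude"] += 1
                continue
            if precision_nm > cfg.max_precision_nm:
                discards["low_precision"] += 1
                continue
            records.append(
                (
                    int(frame),
                    float(x_px) * px,
                    float(y_px) * px,
                    float(amp),
                    float(best.x[-1]),
                    cfg.psf_sigma_nm,
                    precision_nm,
                    best_k,
                )
            )

    table = pd.DataFrame(records, columns=EVENT_TABLE_COLUMNS)
    return table, discards


def merge_consecutive_detections(
    events: pd.DataFrame,
    max_gap_frames: int = 1,
    radius_nm: float = 100.0,
) -> pd.DataFrame:
    """Merge detections of the same release event persisting across frames.

    Detections within ``radius_nm`` of each other and separated by at
    most ``max_gap_frames`` frames are considered one event; the
    earliest detection (brightest on ties) represents the merged event.
    Returns a copy with a ``merged_from`` column counting the raw
    detections behind each row.
    """
    if events.empty:
        out = events.copy()
        out["merged_from"] = pd.Series(dtype=int)
        return out
    ev = events.sort_values(["frame"], kind="stable").reset_index(drop=True)
    n = len(ev)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    frames = ev["frame"].to_numpy()
    xs = ev["x_nm"].to_numpy()
    ys = ev["y_nm"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if frames[j] - frames[i] > max_gap_frames:
                break
            if np.hypot(xs[j] - xs[i], ys[j] - ys[i]) <= radius_nm:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep_rows = []
    for members in groups.values():
        sub = ev.iloc[members]
        first_frame = sub["frame"].min()
        firsts = sub[sub["frame"] == first_frame]
        rep = firsts.sort_values("amplitude", ascending=False).iloc[0].copy()
        rep["merged_from"] = len(members)
        keep_rows.append(rep)
    out = pd.DataFrame(keep_rows).sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
    out["frame"] = out["frame"].astype(int)
    out["merged_from"] = out["merged_from"].astype(int)
    return out


def assign_to_synapses(events: pd.DataFrame, rois) -> pd.DataFrame:
    """Assign each localization to the ROI polygon containing it.

    ``rois`` maps synapse ids to shapely polygons (see
    :class:`relsite.io.RoiSet`). Containment is boundary-inclusive.
    With overlapping ROIs the first match in sorted-id order wins.
    Events outside every ROI get ``synapse_id = None`` (kept in the
    table so unassigned events can be reported).
    """
    from shapely.geometry import Point

    polys = rois.polygons if hasattr(rois, "polygons") else dict(rois)
    ordered = sorted(polys.items(), key=lambda kv: str(kv[0]))
    assigned = []
    for _, row in events.iterrows():
        pt = Point(row["x_nm"], row["y_nm"])
        sid = None
        for name, poly in ordered:
            if poly.covers(pt):
                sid = name
                break
        assigned.append(sid)
    out = events.copy()
    out["synapse_id"] = assigned
    return out
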