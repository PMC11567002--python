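"""Quantification of fluorescence traces from presynaptic reporters.

This module turns raw per-bouton fluorescence time series into the
physiological quantities of interest: ΔF/F₀ normalisation against a
pre-stimulus baseline, single-AP release probability, exo-/endocytosis
rates from train responses, the endocytic time constant τ from a
single-exponential fit of the post-stimulus decay, the fractional
retrieval block ΔF_2τ / ΔF_max, and peak responses of step-perfused
metabolite sensors.

Frame windows are half-open ``(start, stop)`` index ranges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class NonDecayingError(RuntimeError):
    """Raised when a post-stimulus segment does not decay and no exponential fit is meaningful."""


@dataclass
class Trace:
    """A fluorescence time series with baseline and stimulus annotations.

    Parameters
    ----------
    values : array of fluorescence values (a.u.), one per frame.
    frame_interval_s : acquisition interval in seconds.
    baseline : half-open frame range ``(start, stop)`` recorded before stimulation.
    stimulus : half-open frame range covering the stimulus train.
    """

    values: np.ndarray
    frame_interval_s: float
    baseline: tuple[int, int]
    stimulus: tuple[int, int]
    roi_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        n = self.values.size
        b0, b1 = self.baseline
        s0, s1 = self.stimulus
        if not (0 <= b0 <= b1 <= n and 0 <= s0 <= s1 <= n):
            raise ValueError("baseline/stimulus windows must lie within the trace")
        if b1 > s0:
            raise ValueError("baseline window must precede the stimulus window")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def time_s(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.values.size) * self.frame_interval_s


@dataclass
class EndoFit:
    """Result of a single-exponential fit to the post-stimulus decay.

    ``tau_s`` is the endocytic time constant, ``delta_f_max`` the
    fluorescence change at the end of stimulation (the fit's amplitude),
    ``f_inf`` the fitted asymptote. ``converged`` is False for fits that
    failed, hit the τ bounds, or were otherwise unusable.
    """

    tau_s: float
    delta_f_max: float
    f_inf: float
    converged: bool
    residual_norm: float
    message: str = ""


def normalize_dff(trace: Trace) -> np.ndarray:
    """Return the ΔF/F₀ series, with F₀ the mean over the baseline window.

    Raises
    ------
    ValueError
        If the baseline window is empty or its mean is not positive
        (which signals a bad ROI or over-subtracted background).
    """
    b0, b1 = trace.baseline
    if b1 <= b0:
        raise ValueError("baseline window is empty")
    f0 = float(np.mean(trace.values[b0:b1]))
    if f0 <= 0:
        raise ValueError(f"baseline mean F0 = {f0:g} is not positive; check ROI/background subtraction")
    return (trace.values - f0) / f0


def release_probability(n_events: int, protocol) -> float:
    """Single-AP release probability: events per stimulus pulse.

    Values above 1 are legitimate for multi-site active zones (more than
    one vesicle can fuse per action potential) and are returned as-is.
    """
    if protocol.n_pulses <= 0:
        raise ValueError("protocol must contain at least one pulse")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return n_events / protocol.n_pulses


def exo_endo_rates(
    dff: np.ndarray,
    stimulus: tuple[int, int],
    frame_interval_s: float,
    decay_frames: int | None = None,
) -> tuple[float, float]:
    """Rise and decay rates (ΔF/F₀ per second) of a train response.

    Both are least-squares line slopes: the rise over the stimulus
    window, the decay over the first ``decay_frames`` frames after the
    stimulus (default: as many frames as the stimulus window, capped at
    what the trace holds). The decay slope is returned signed
    (negative for a decaying trace).
    """
    dff = np.asarray(dff, dtype=float)
    s0, s1 = stimulus
    if s1 - s0 < 3:
        raise ValueError("stimulus window must span at least 3 frames")
    t = np.arange(dff.size) * frame_interval_s
    rise = np.polyfit(t[s0:s1], dff[s0:s1], 1)[0]

    if decay_frames is None:
        decay_frames = s1 - s0
    d1 = min(dff.size, s1 + decay_frames)
    if d1 - s1 < 3:
        raise ValueError("post-stimulus segment must span at least 3 frames")
    decay = np.polyfit(t[s1:d1], dff[s1:d1], 1)[0]
    return float(rise), float(decay)


def fit_endocytic_tau(
    dff: np.ndarray,
    stimulus: tuple[int, int],
    frame_interval_s: float,
    anchored: bool = True,
) -> EndoFit:
    """Fit ``f_inf + dF·exp(-(t-t_end)/τ)`` to the post-stimulus segment.

    With ``anchored=True`` (default) the amplitude is anchored so the
    model passes through the measured value at the end of stimulation
    (dF = dff[t_end] - f_inf), matching the convention that ΔF_max is
    the fluorescence change at the last stimulus frame; with
    ``anchored=False`` amplitude, asymptote and τ are all free.

    τ is bounded in (0, 10 × segment length]; a fit pinned at the upper
    bound or failing to converge is returned with ``converged=False``.

    Raises
    ------
    NonDecayingError
        If the post-stimulus segment is flat or rising overall.
    """
    dff = np.asarray(dff, dtype=float)
    s1 = stimulus[1]
    seg = dff[s1 - 1 :]  # include the end-of-stimulation frame as t=0
    if seg.size < 6:
        raise ValueError("need at least 5 post-stimulus frames to fit a decay")
    t = np.arange(seg.size) * frame_interval_s
    slope = np.polyfit(t, seg, 1)[0]
    if slope >= 0:
        raise NonDecayingError("post-stimulus segment does not decay; no endocytic time constant")

    f_end = seg[0]
    seg_len = t[-1]
    tau_hi = 10.0 * seg_len
    tau0 = min(max(seg_len / 3.0, frame_interval_s), tau_hi / 2)

    if anchored:
        def resid(p):
            tau, f_inf = p
            return f_inf + (f_end - f_inf) * np.exp(-t / tau) - seg

        x0 = np.array([tau0, min(seg.min(), f_end - 1e-12)])
        lb = [1e-9, -np.inf]
        ub = [tau_hi, f_end]
    else:
        def resid(p):
            tau, f_inf, df = p
            return f_inf + df * np.exp(-t / tau) - seg

        x0 = np.array([tau0, seg.min(), f_end - seg.min()])
        lb = [1e-9, -np.inf, 0.0]
        ub = [tau_hi, np.inf, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    tau = float(sol.x[0])
    f_inf = float(sol.x[1])
    df = f_end - f_inf if anchored else float(sol.x[2])
    converged = bool(sol.success) and tau < 0.999 * tau_hi and df >= 0
    return EndoFit(
        tau_s=tau,
        delta_f_max=float(df),
        f_inf=f_inf,
        converged=converged,
        residual_norm=float(np.linalg.norm(sol.fun)),
        message=sol.message,
    )


def fractional_retrieval_block(
    dff: np.ndarray,
    control_tau_s: float,
    stimulus: tuple[int, int],
    frame_interval_s: float,
    f_inf_referenced: bool = False,
    f_inf: float = 0.0,
) -> float:
    """ΔF remaining at two control time-constants after stimulation, over ΔF_max.

    ΔF_max is the ΔF/F₀ value at the last stimulus frame; the numerator
    is the (linearly interpolated) value at t_end + 2·control τ. The
    control τ is the mean endocytic time constant of the designated
    control group and is applied to every group. 0 means complete
    retrieval within 2τ of the control, 1 means fully blocked
    endocytosis. By default ΔF is referenced to baseline (ΔF/F₀ = 0);
    set ``f_inf_referenced=True`` to reference both numerator and
    denominator to a supplied asymptote instead.
    """
    if control_tau_s <= 0:
        raise ValueError("control_tau_s must be positive")
    dff = np.asarray(dff, dtype=float)
    s1 = stimulus[1]
    t_end = (s1 - 1) * frame_interval_s
    t_query = t_end + 2.0 * control_tau_s
    t_last = (dff.size - 1) * frame_interval_s
    if t_query > t_last + 1e-9:
        raise ValueError(
            f"trace ends at {t_last:g} s but the retrieval block needs the value at "
            f"{t_query:g} s (stimulus end + 2x control tau); extend the recording"
        )
    t = np.arange(dff.size) * frame_interval_s
    ref = f_inf if f_inf_referenced else 0.0
    df_max = dff[s1 - 1] - ref
    if df_max <= 0:
        raise ValueError("ΔF at end of stimulation is not positive; no response to quantify")
    df_2tau = float(np.interp(t_query, t, dff)) - ref
    return float(df_2tau / df_max)


def peak_response(
    dff: np.ndarray,
    window: tuple[int, int],
    smooth_frames: int = 3,
) -> tuple[float, bool]:
    """Peak ΔF/F₀ within a response window, with light smoothing.

    A moving mean of ``smooth_frames`` frames (default 3) is applied
    before taking the maximum, because the raw maximum of a noisy trace
    is upward-biased; pass ``smooth_frames=1`` for the raw maximum.
    Returns ``(peak, negative_flag)``: the flag is True when the peak
    itself is negative (an inverted or absent response).
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("response window is empty")
    if smooth_frames < 1:
        raise ValueError("smooth_frames must be >= 1")
    dff = np.asarray(dff, dtype=float)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        smoothed = np.convolve(dff, kernel, mode="same")
    else:
        smoothed = dff
    peak = float(np.max(smoothed[w0:w1]))
    return peak, peak < 0


def channel_ratio(
    numerator: np.ndarray,
    denominator: np.ndarray,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Frame-wise ratio of two channels and its mean over a window.

    Used for ratiometric sensors where the analyte signal (e.g. a GFP
    channel) is normalised by an analyte-insensitive channel (e.g. far
    red) to cancel expression differences.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator traces must have equal length")
    if np.any(den <= 0):
        raise ValueError("denominator trace must be strictly positive")
    ratio = num / den
    if window is None:
        window = (0, ratio.size)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("ratio window is empty")
    return ratio, float(np.mean(ratio[w0:w1]))
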