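"""Synthetic ground truth for the release-mapping and kinetics pipeline.

Everything downstream of raw acquisition can be exercised on data
generated here: active zones (AZs) with planted release sites, Bernoulli
event streams driven by a stimulus protocol, near-TIRF-like movies with
an integrated-Gaussian point-spread function and Poisson photon noise,
pHluorin train responses with single-exponential endocytic decay, and
step responses of a perfused metabolite sensor.

Defaults mirror the experimental conditions the pipeline was designed
for: 50 ms frames for single-vesicle movies, 0.5 s frames (2 Hz) for
pHluorin traces, 30 baseline frames before the stimulus train, and
27 nm localization noise on observed event positions.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .kinetics import Trace


@dataclass(frozen=True)
class StimulusProtocol:
    """A field-stimulation protocol plus the acquisition timing around it.

    ``n_pulses`` action potentials at ``frequency`` Hz, imaged at one
    frame per ``frame_interval`` seconds, with ``n_baseline_frames``
    recorded before the train starts.
    """

    n_pulses: int
    frequency: float
    frame_interval: float
    n_baseline_frames: int = 30

    def __post_init__(self) -> None:
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_baseline_frames < 0:
            raise ValueError("n_baseline_frames must be >= 0")

    @property
    def stimulus_duration_s(self) -> float:
        return self.n_pulses / self.frequency

    @property
    def n_stimulus_frames(self) -> int:
        return int(np.ceil(self.stimulus_duration_s / self.frame_interval))

    def pulse_times_s(self) -> np.ndarray:
        """Pulse times in seconds from the start of the recording."""
        onset = self.n_baseline_frames * self.frame_interval
        return onset + np.arange(self.n_pulses) / self.frequency


# Protocols used throughout: single-AP mapping (1 Hz for 200 s at 50 ms
# frames) and pHluorin trains (100 AP @ 10 Hz or 50 AP @ 40 Hz at 2 Hz
# imaging with 30 baseline frames).
SINGLE_AP_PROTOCOL = StimulusProtocol(n_pulses=200, frequency=1.0, frame_interval=0.05)
TRAIN_100AP_10HZ = StimulusProtocol(n_pulses=100, frequency=10.0, frame_interval=0.5)
TRAIN_50AP_40HZ = StimulusProtocol(n_pulses=50, frequency=40.0, frame_interval=0.5)

DEFAULT_LOCALIZATION_SIGMA_NM = 27.0


@dataclass(frozen=True)
class GroundTruthAZ:
    """An active zone with planted release sites.

    ``site_positions`` are true site coordinates in nm relative to the
    AZ origin; ``site_release_rates`` are per-site probabilities of a
    release event per stimulus pulse; ``localization_sigma`` is the
    isotropic Gaussian SD added to true positions to produce observed
    (localized) positions.
    """

    site_positions: np.ndarray
    site_release_rates: np.ndarray
    az_radius: float
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA_NM

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.site_positions, dtype=float))
        rates = np.atleast_1d(np.asarray(self.site_release_rates, dtype=float))
        object.__setattr__(self, "site_positions", pos)
        object.__setattr__(self, "site_release_rates", rates)
        if pos.shape[1] != 2:
            raise ValueError("site_positions must be an (n, 2) array of nm coordinates")
        if rates.shape[0] != pos.shape[0]:
            raise ValueError("one release rate per site is required")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("release rates must lie in [0, 1]")
        if self.az_radius <= 0:
            raise ValueError("az_radius must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > self.az_radius + 1e-9):
            raise ValueError("all site positions must lie within az_radius of the origin")

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]


@dataclass(frozen=True)
class GroundTruthTrace:
    """Hidden parameters of a synthetic pHluorin train response.

    ``f0`` baseline fluorescence (a.u.), ``delta_f_max`` the train
    amplitude reached at the end of stimulation, ``tau_endo`` the
    endocytic decay constant in seconds, ``noise_sd`` additive Gaussian
    noise. The rise is linear over the stimulus window, so the rise
    rate is delta_f_max divided by the stimulus duration.
    """

    f0: float
    delta_f_max: float
    tau_endo: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.tau_endo <= 0:
            raise ValueError("tau_endo must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.delta_f_max < 0:
            raise ValueError("delta_f_max must be >= 0")


@dataclass
class Movie:
    """A stack of frames on a photon-count scale with calibration metadata."""

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be frames x rows x cols")
        if np.any(self.data < 0):
            raise ValueError("pixel values must be non-negative (photon-count scale)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def make_az(
    n_sites: int,
    az_radius: float,
    rate_profile,
    seed: int,
    min_spacing: float = 60.0,
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA_NM,
    max_restarts: int = 500,
) -> GroundTruthAZ:
    """Place ``n_sites`` release sites uniformly in a disk of radius ``az_radius``.

    Sites are drawn by rejection sampling with a minimum pairwise
    spacing (default 60 nm, just above the 50 nm clustering diameter so
    planted sites are resolvable by construction).

    Raises
    ------
    ValueError
        If the requested spacing cannot be satisfied inside the disk
        after ``max_restarts`` independent sequential attempts.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if az_radius <= 0:
        raise ValueError("az_radius must be positive")
    rates = np.atleast_1d(np.asarray(rate_profile, dtype=float))
    if rates.shape[0] != n_sites:
        raise ValueError(f"rate_profile has length {rates.shape[0]}, expected {n_sites}")
    rng = np.random.default_rng(seed)

    attempts_per_site = 200
    for _ in range(max_restarts):
        placed: list[np.ndarray] = []
        for _ in range(n_sites):
            ok = False
            for _ in range(attempts_per_site):
                r = az_radius * np.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * np.pi)
                p = np.array([r * np.cos(theta), r * np.sin(theta)])
                if all(np.hypot(*(p - q)) >= min_spacing for q in placed):
                    placed.append(p)
                    ok = True
                    break
            if not ok:
                break
        if len(placed) == n_sites:
            return GroundTruthAZ(
                site_positions=np.array(placed),
                site_release_rates=rates,
                az_radius=az_radius,
                localization_sigma=localization_sigma,
            )
    raise ValueError(
        f"cannot place {n_sites} sites with minimum spacing {min_spacing} nm "
        f"inside a disk of radius {az_radius} nm"
    )


# Column dictionary for event streams (all distances in nm, times in s):
#   pulse       stimulus pulse index (0-based)
#   time_s      pulse time from the start of the recording
#   frame       movie frame the event falls into
#   site        index of the releasing site in the ground-truth AZ
#   true_x_nm/true_y_nm   true site position
#   x_nm/y_nm   observed position (true + isotropic localization noise)
EVENT_COLUMNS = ["pulse", "time_s", "frame", "site", "true_x_nm", "true_y_nm", "x_nm", "y_nm"]


def sample_events(az: GroundTruthAZ, protocol: StimulusProtocol, seed: int):
    """Draw a release-event stream from an AZ under a stimulus protocol.

    Each site releases independently at each pulse with its own rate —
    at most one event per site per pulse. Observed positions are the
    true site positions plus isotropic Gaussian noise with SD
    ``az.localization_sigma``. Returns a DataFrame with the columns in
    :data:`EVENT_COLUMNS`, ordered by pulse then site.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    times = protocol.pulse_times_s()
    released = rng.uniform(size=(protocol.n_pulses, az.n_sites)) < az.site_release_rates[None, :]
    pulse_idx, site_idx = np.nonzero(released)
    true_pos = az.site_positions[site_idx]
    noise = rng.normal(scale=az.localization_sigma, size=true_pos.shape) if az.localization_sigma > 0 else 0.0
    obs = true_pos + noise
    t = times[pulse_idx] if pulse_idx.size else np.empty(0)
    frames = np.floor(t / protocol.frame_interval).astype(int) if pulse_idx.size else np.empty(0, dtype=int)
    return pd.DataFrame(
        {
            "pulse": pulse_idx,
            "time_s": t,
            "frame": frames,
            "site": site_idx,
            "true_x_nm": true_pos[:, 0] if pulse_idx.size else np.empty(0),
            "true_y_nm": true_pos[:, 1] if pulse_idx.size else np.empty(0),
            "x_nm": obs[:, 0] if pulse_idx.size else np.empty(0),
            "y_nm": obs[:, 1] if pulse_idx.size else np.empty(0),
        }
    )


def _integrated_gaussian_patch(x_px, y_px, sigma_px, cols, rows):
    """Photon fraction of a unit Gaussian at (x_px, y_px) in each listed pixel.

    Pixel (r, c) spans [c - 0.5, c + 0.5] x [r - 0.5, r + 0.5] in pixel
    units — the coordinate origin is the centre of pixel (0, 0), x runs
    along columns and y along rows.
    """
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x_px) / s) - erf((cols - 0.5 - x_px) / s))
    fy = 0.5 * (erf((rows + 0.5 - y_px) / s) - erf((rows - 0.5 - y_px) / s))
    return fy[:, None] * fx[None, :]


def render_movie(
    events,
    psf_sigma: float,
    photons_per_event: float,
    background: float,
    pixel_size: float,
    shape: tuple[int, int],
    seed: int,
    n_frames: int | None = None,
    frame_interval_s: float = 0.05,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    out_of_fov: str = "clip",
    poisson_noise: bool = True,
) -> Movie:
    """Render an event stream into a photon-count movie.

    Each event contributes an integrated 2D Gaussian of width
    ``psf_sigma`` (nm) carrying ``photons_per_event`` photons at its
    observed position in its frame, on a uniform ``background``
    (photons/pixel/frame). Poisson noise is applied to signal plus
    background unless ``poisson_noise=False`` (useful for exact tests).

    ``origin_nm`` maps event coordinates into the field of view: an
    event at ``origin_nm`` lands at the centre of pixel (0, 0). Events
    outside the field of view are clipped with a warning by default;
    pass ``out_of_fov="error"`` to fail instead.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if photons_per_event <= 0:
        raise ValueError("photons_per_event must be positive")
    if background < 0:
        raise ValueError("background must be >= 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if out_of_fov not in ("clip", "error"):
        raise ValueError("out_of_fov must be 'clip' or 'error'")

    rows, cols = shape
    if n_frames is None:
        n_frames = int(events["frame"].max()) + 1 if len(events) else 1
    signal = np.zeros((n_frames, rows, cols), dtype=float)
    sigma_px = psf_sigma / pixel_size
    half = max(3, int(np.ceil(5 * sigma_px)))

    n_clipped = 0
    for frame, x_nm, y_nm in zip(events["frame"], events["x_nm"], events["y_nm"]):
        x_px = (x_nm - origin_nm[0]) / pixel_size
        y_px = (y_nm - origin_nm[1]) / pixel_size
        inside = -0.5 <= x_px <= cols - 0.5 and -0.5 <= y_px <= rows - 0.5
        if not inside:
            if out_of_fov == "error":
                raise ValueError(f"event at ({x_nm:g}, {y_nm:g}) nm falls outside the field of view")
            n_clipped += 1
            continue
        if not 0 <= frame < n_frames:
            raise ValueError(f"event frame {frame} outside movie of {n_frames} frames")
        c0, c1 = max(0, int(np.floor(x_px)) - half), min(cols, int(np.ceil(x_px)) + half + 1)
        r0, r1 = max(0, int(np.floor(y_px)) - half), min(rows, int(np.ceil(y_px)) + half + 1)
        patch = _integrated_gaussian_patch(x_px, y_px, sigma_px, np.arange(c0, c1), np.arange(r0, r1))
        signal[frame, r0:r1, c0:c1] += photons_per_event * patch
    if n_clipped:
        warnings.warn(f"{n_clipped} event(s) outside the field of view were clipped", stacklevel=2)

    expected = signal + background
    if poisson_noise:
        rng = np.random.default_rng(seed)
        data = rng.poisson(expected).astype(float)
    else:
        data = expected
    return Movie(data=data, pixel_size_nm=pixel_size, frame_interval_s=frame_interval_s)


def simulate_phluorin_trace(
    gt: GroundTruthTrace,
    protocol: StimulusProtocol,
    seed: int,
    n_decay_frames: int | None = None,
) -> Trace:
    """Simulate a vesicle-lumen pHluorin train response.

    Baseline at ``f0`` for the protocol's baseline frames, a linear rise
    to ``f0 + delta_f_max`` across the stimulus window (exocytosis
    dominating), then a single-exponential return to baseline with time
    constant ``tau_endo`` (re-acidification after endocytic retrieval).
    Additive Gaussian noise with SD ``noise_sd``. The decay segment
    covers five time constants unless ``n_decay_frames`` is given.
    """
    nb = protocol.n_baseline_frames
    ns = protocol.n_stimulus_frames
    if n_decay_frames is None:
        n_decay_frames = int(np.ceil(5.0 * gt.tau_endo / protocol.frame_interval)) + 1
    n = nb + ns + n_decay_frames
    values = np.full(n, gt.f0, dtype=float)
    if ns > 0:
        values[nb : nb + ns] = gt.f0 + gt.delta_f_max * (np.arange(1, ns + 1) / ns)
    t_after = np.arange(1, n_decay_frames + 1) * protocol.frame_interval
    values[nb + ns :] = gt.f0 + gt.delta_f_max * np.exp(-t_after / gt.tau_endo)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(scale=gt.noise_sd, size=n)
    return Trace(
        values=values,
        frame_interval_s=protocol.frame_interval,
        baseline=(0, nb),
        stimulus=(nb, nb + ns),
    )


def simulate_step_sensor_trace(
    baseline_f: float,
    plateau_dff: float,
    on_frame: int,
    off_frame: int,
    kinetic_tau: float,
    noise_sd: float,
    seed: int,
    frame_interval_s: float = 1.0,
    n_frames: int | None = None,
) -> Trace:
    """Simulate a metabolite-sensor response to a perfusion step.

    Models a 0 → analyte → 0 perfusion switch (e.g. 0 → 10 → 0 mM
    pyruvate on a matrix-targeted pyruvate sensor): mono-exponential
    approach to ``baseline_f * (1 + plateau_dff)`` after ``on_frame``
    and mono-exponential return to baseline after ``off_frame``, both
    with time constant ``kinetic_tau`` seconds.
    """
    if baseline_f <= 0:
        raise ValueError("baseline_f must be positive")
    if on_frame >= off_frame:
        raise ValueError("on_frame must precede off_frame")
    if kinetic_tau <= 0:
        raise ValueError("kinetic_tau must be positive")
    if n_frames is None:
        n_frames = off_frame + int(np.ceil(5.0 * kinetic_tau / frame_interval_s)) + 1
    t = np.arange(n_frames) * frame_interval_s
    t_on = on_frame * frame_interval_s
    t_off = off_frame * frame_interval_s
    dff = np.zeros(n_frames)
    during = (t >= t_on) & (t < t_off)
    dff[during] = plateau_dff * (1.0 - np.exp(-(t[during] - t_on) / kinetic_tau))
    dff_off = plateau_dff * (1.0 - np.exp(-(t_off - t_on) / kinetic_tau))
    after = t >= t_off
    dff[after] = dff_off * np.exp(-(t[after] - t_off) / kinetic_tau)
    values = baseline_f * (1.0 + dff)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(scale=noise_sd, size=n_frames)
    return Trace(
        values=values,
        frame_interval_s=frame_interval_s,
        baseline=(0, on_frame),
        stimulus=(on_frame, off_frame),
    )
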