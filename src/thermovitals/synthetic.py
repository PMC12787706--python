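"""Ground-truth-labelled phantom recordings for end-to-end pipeline testing.

The generators emulate the statistical structure of a fixed-head frontal
thermal recording without any radiometric gas physics:

* MWIR phantom — a warm face ellipse on an ambient background, two hot
  inner-canthus spots carrying a milli-kelvin cardiac oscillation, and a dark
  exhaled-CO2 plume below the nostrils that is advected downward at a
  configurable velocity during each expiration, plus white sensor noise.
* LWIR phantom — the same face, with a capnogram-like nostril temperature
  waveform (sharp upstroke, plateau, downstroke, baseline) in phase with
  expiration, i.e. opposite in sign to the MWIR plume signal.
* PPG trace — cardiac fundamental plus harmonic with a respiratory baseline
  modulation, at the pulse oximeter's native 409.6 Hz.
* Standalone STIs — parallel streaks of known slope for velocimetry unit
  tests.

The plume is a parcel-advection model: the pixel at distance ``x`` below a
nostril is darkened at time ``t`` iff its emission time ``t - x/v`` fell
inside an exhalation; a slow sinusoidal texture on the emission time produces
parallel streaks of slope exactly ``v`` in a space-time image.  The whole
puff must stay inside the frame for the duration of one expiration, which is
why the phantom uses a deliberately coarse pixel scale (auto-fitted by
default).  All randomness flows from ``PhantomConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .io_thermal import ThermalStack, TimeSeriesSignal
from .signals import RectROI
from .stiv import LineROI, SpaceTimeImage

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_mwir_phantom",
    "generate_lwir_phantom",
    "generate_ppg",
    "generate_sti",
    "default_resp_roi",
    "default_nostril_rois",
    "default_stiv_line",
]

PPG_FS_HZ = 409.6  # pulse oximeter native sampling rate


@dataclass
class PhantomConfig:
    """Parameters of the synthetic recording; defaults emulate the acquisition
    conditions the pipeline targets (40 s spontaneous breathing at 60 fps,
    ~24 degC room, 18 mK sensor noise).

    ``pixel_scale_m_per_px=None`` auto-fits the scale so one exhaled puff
    exactly spans the sub-nostril field during an expiration.
    """

    duration_s: float = 40.0
    fps: float = 60.0
    height_px: int = 96
    width_px: int = 80
    pixel_scale_m_per_px: float | None = None
    ambient_C: float = 24.0
    face_temp_C: float = 34.0
    canthus_temp_C: float = 36.5
    canthus_centres: tuple = ((28, 30), (28, 50))
    canthus_radius_px: int = 3
    pulse_amp_mK: float = 30.0
    heart_rate_bpm: float = 72.0
    resp_rate_bpm: float = 15.0
    exhale_fraction: float = 0.5
    nostril_centres: tuple = ((44, 36), (44, 44))
    nostril_area_m2: tuple = (7.18e-5, 5.85e-5)
    plume_velocity_m_per_s: float = 1.0
    plume_absorption_depth_C: float = 0.5
    plume_sigma_px: float = 2.5
    plume_texture_hz: float = 2.0
    lwir_nostril_amp_C: float = 1.0
    lwir_nostril_base_C: float = 30.0
    lwir_fps: float = 30.0
    noise_sd_mK: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.resp_rate_bpm < self.heart_rate_bpm:
            raise ValueError("need 0 < resp_rate_bpm < heart_rate_bpm")
        if self.duration_s * self.resp_rate_bpm / 60.0 < 4:
            raise ValueError("recording must span at least 4 respiratory cycles")
        if not 0 < self.exhale_fraction < 1:
            raise ValueError("exhale_fraction must lie in (0, 1)")
        for name in (
            "pulse_amp_mK",
            "plume_absorption_depth_C",
            "lwir_nostril_amp_C",
            "noise_sd_mK",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.plume_velocity_m_per_s <= 0:
            raise ValueError("plume velocity must be positive")
        # plume must not exit the frame before the end of an expiration
        if self.pixel_scale_m_per_px is not None:
            travel_px = (
                self.plume_velocity_m_per_s
                * self.exhale_duration_s
                / self.pixel_scale_m_per_px
            )
            if travel_px > self.plume_channel_px:
                raise ValueError(
                    f"plume would exit the frame before end of expiration: "
                    f"{travel_px:.1f} px travel > {self.plume_channel_px} px below nostrils; "
                    f"increase pixel_scale_m_per_px or shorten the expiration"
                )

    @property
    def resp_period_s(self) -> float:
        return 60.0 / self.resp_rate_bpm

    @property
    def exhale_duration_s(self) -> float:
        return self.exhale_fraction * self.resp_period_s

    @property
    def plume_channel_px(self) -> int:
        """Rows available below the nostrils for the plume."""
        nostril_row = max(r for r, _ in self.nostril_centres)
        return (self.height_px - 2) - nostril_row

    @property
    def resolved_pixel_scale(self) -> float:
        if self.pixel_scale_m_per_px is not None:
            return self.pixel_scale_m_per_px
        return (
            self.plume_velocity_m_per_s
            * self.exhale_duration_s
            / self.plume_channel_px
        )

    def exhalation_windows(self) -> list[tuple[float, float]]:
        """(start, end) seconds of each expiration; expiration opens each cycle."""
        windows = []
        k = 0
        while k * self.resp_period_s < self.duration_s:
            t0 = k * self.resp_period_s
            t1 = min(t0 + self.exhale_duration_s, self.duration_s)
            windows.append((t0, t1))
            k += 1
        return windows


@dataclass
class GroundTruth:
    """True parameter values of a phantom, for recovery testing."""

    resp_rate_bpm: float
    heart_rate_bpm: float
    body_temp_C: float
    plume_velocity_m_per_s: float
    exhalation_windows: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["exhalation_windows"] = [tuple(w) for w in d["exhalation_windows"]]
        return cls(**d)


def _base_face(config: PhantomConfig) -> np.ndarray:
    """Static scene: blurred face ellipse on ambient, flat canthus disks."""
    h, w = config.height_px, config.width_px
    rows, cols = np.ogrid[:h, :w]
    base = np.full((h, w), config.ambient_C, dtype=np.float64)
    rc, cc = 0.38 * h, 0.5 * w
    ra, ca = 0.34 * h, 0.32 * w
    ellipse = ((rows - rc) / ra) ** 2 + ((cols - cc) / ca) ** 2 <= 1.0
    base[ellipse] = config.face_temp_C
    base = ndi.gaussian_filter(base, 1.5)
    for r0, c0 in config.canthus_centres:
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= config.canthus_radius_px**2
        base[disk] = config.canthus_temp_C
    return base


def _canthus_mask(config: PhantomConfig) -> np.ndarray:
    h, w = config.height_px, config.width_px
    rows, cols = np.ogrid[:h, :w]
    mask = np.zeros((h, w), dtype=bool)
    for r0, c0 in config.canthus_centres:
        mask |= (rows - r0) ** 2 + (cols - c0) ** 2 <= config.canthus_radius_px**2
    return mask


def _ground_truth(config: PhantomConfig) -> GroundTruth:
    return GroundTruth(
        resp_rate_bpm=config.resp_rate_bpm,
        heart_rate_bpm=config.heart_rate_bpm,
        body_temp_C=config.canthus_temp_C,
        plume_velocity_m_per_s=config.plume_velocity_m_per_s,
        exhalation_windows=config.exhalation_windows(),
    )


def generate_mwir_phantom(config: PhantomConfig) -> tuple[ThermalStack, GroundTruth]:
    """Synthesize the MWIR recording: face + pulsing canthi + advected dark plume."""
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.fps))
    t = np.arange(n_frames) / config.fps
    h, w = config.height_px, config.width_px
    scale = config.resolved_pixel_scale

    frames = np.broadcast_to(_base_face(config), (n_frames, h, w)).copy()

    # cardiac oscillation on the (flat) canthus disks
    cmask = _canthus_mask(config)
    pulse = (config.pulse_amp_mK / 1000.0) * np.sin(
        2 * np.pi * (config.heart_rate_bpm / 60.0) * t
    )
    frames[:, cmask] += pulse[:, None]

    # exhaled plume: parcel at distance x was emitted at t_e = t - x/v and is
    # dark iff t_e fell inside an expiration (first exhale_fraction of cycle)
    if config.plume_absorption_depth_C > 0:
        v = config.plume_velocity_m_per_s
        period = config.resp_period_s
        t_ex = config.exhale_duration_s
        cols = np.arange(w)
        for r_n, c_n in config.nostril_centres:
            rows_below = np.arange(r_n + 1, h - 1)
            x_m = (rows_below - r_n) * scale
            t_e = t[:, None] - x_m[None, :] / v  # (T, R)
            active = (t_e >= 0) & (np.mod(t_e, period) < t_ex)
            texture = 0.7 + 0.3 * np.sin(2 * np.pi * config.plume_texture_hz * t_e)
            depth = config.plume_absorption_depth_C * active * texture
            profile = np.exp(-0.5 * ((cols - c_n) / config.plume_sigma_px) ** 2)
            frames[:, rows_below, :] -= depth[:, :, None] * profile[None, None, :]

    if config.noise_sd_mK > 0:
        frames += rng.normal(0.0, config.noise_sd_mK / 1000.0, frames.shape)

    stack = ThermalStack(
        frames=frames,
        fps=config.fps,
        pixel_scale=scale,
        modality="SYNTHETIC",
        origin_note=f"MWIR phantom (seed {config.seed})",
    )
    return stack, _ground_truth(config)


def _capnogram_waveform(phase: np.ndarray, exhale_fraction: float) -> np.ndarray:
    """Normalized nostril-temperature waveform over one cycle, phase in [0, 1).

    Expiration (first ``exhale_fraction`` of the cycle): sharp upstroke to 0.85
    then a slow climb to the plateau peak of 1; inspiration: sharp downstroke
    back to the 0 baseline.
    """
    e = exhale_fraction
    rise_end = 0.2 * e
    fall_end = e + 0.2 * (1 - e)
    w = np.zeros_like(phase)
    m = phase < rise_end
    w[m] = 0.85 * phase[m] / rise_end
    m = (phase >= rise_end) & (phase < e)
    w[m] = 0.85 + 0.15 * (phase[m] - rise_end) / (e - rise_end)
    m = (phase >= e) & (phase < fall_end)
    w[m] = 1.0 - (phase[m] - e) / (fall_end - e)
    return w


def generate_lwir_phantom(config: PhantomConfig) -> tuple[ThermalStack, GroundTruth]:
    """Synthesize the LWIR reference recording: capnogram-like nostril waveform."""
    rng = np.random.default_rng(config.seed + 1)
    n_frames = int(round(config.duration_s * config.lwir_fps))
    t = np.arange(n_frames) / config.lwir_fps
    h, w = config.height_px, config.width_px

    base = _base_face(config)
    rows, cols = np.ogrid[:h, :w]
    nmask = np.zeros((h, w), dtype=bool)
    for r0, c0 in config.nostril_centres:
        nmask |= (rows - r0) ** 2 + (cols - c0) ** 2 <= 2**2
    base[nmask] = config.lwir_nostril_base_C

    frames = np.broadcast_to(base, (n_frames, h, w)).copy()
    phase = np.mod(t * config.resp_rate_bpm / 60.0, 1.0)
    wave = config.lwir_nostril_amp_C * _capnogram_waveform(phase, config.exhale_fraction)
    frames[:, nmask] += wave[:, None]
    if config.noise_sd_mK > 0:
        # LWIR microbolometers are noisier than the MWIR sensor; 5x NETD
        frames += rng.normal(0.0, 5 * config.noise_sd_mK / 1000.0, frames.shape)

    stack = ThermalStack(
        frames=frames,
        fps=config.lwir_fps,
        pixel_scale=config.resolved_pixel_scale,
        modality="SYNTHETIC",
        origin_note=f"LWIR phantom (seed {config.seed})",
    )
    return stack, _ground_truth(config)


def generate_ppg(config: PhantomConfig, fs: float = PPG_FS_HZ) -> TimeSeriesSignal:
    """Pulse-oximeter trace sharing the phantom's cardiac/respiratory frequencies."""
    rng = np.random.default_rng(config.seed + 2)
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    f_h = config.heart_rate_bpm / 60.0
    f_r = config.resp_rate_bpm / 60.0
    values = (
        np.sin(2 * np.pi * f_h * t)
        + 0.3 * np.sin(4 * np.pi * f_h * t)
        + 0.25 * np.sin(2 * np.pi * f_r * t)
        + rng.normal(0.0, 0.05, n)
    )
    return TimeSeriesSignal(values, fs=fs, label="ppg")


def generate_sti(
    slope_px_per_frame: float,
    n_time: int,
    n_space: int,
    streak_spacing_px: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
    sx: float = 1.0,
    st: float = 1.0,
) -> SpaceTimeImage:
    """Parallel dark streaks advancing ``slope_px_per_frame`` px of space per
    time step; ground-truth angle theta = atan(1/slope) from the space axis."""
    if slope_px_per_frame <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)
    tt = np.arange(n_time)[:, None]
    xx = np.arange(n_space)[None, :]
    phase = 2 * np.pi * (xx - slope_px_per_frame * tt) / streak_spacing_px
    values = 0.5 - 0.5 * np.cos(phase)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    return SpaceTimeImage(
        values, sx=sx, st=st, provenance=f"synthetic STI slope {slope_px_per_frame}"
    )


def default_resp_roi(config: PhantomConfig) -> RectROI:
    """Rectangle over the visualized exhalation, just below both nostrils."""
    r_n = max(r for r, _ in config.nostril_centres)
    c_lo = min(c for _, c in config.nostril_centres)
    c_hi = max(c for _, c in config.nostril_centres)
    return RectROI(
        row0=r_n + 2,
        col0=max(0, c_lo - 6),
        row1=min(config.height_px, r_n + 18),
        col1=min(config.width_px, c_hi + 7),
    )


def default_nostril_rois(config: PhantomConfig, half: int = 2) -> list[RectROI]:
    """One small rectangle per nostril (LWIR reference signal)."""
    rois = []
    for r, c in config.nostril_centres:
        rois.append(RectROI(r - half, c - half, r + half + 1, c + half + 1))
    return rois


def default_stiv_line(config: PhantomConfig, nostril: int = 0) -> LineROI:
    """Vertical sampling line from just below a nostril to the bottom margin."""
    r_n, c_n = config.nostril_centres[nostril]
    return LineROI(r_n + 1, c_n, config.height_px - 2, c_n)
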