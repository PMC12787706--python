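"""Space-time image velocimetry (STIV) for exhaled-airflow estimation.

A line ROI is placed along the visible plume below a nostril and the stack is
resliced along it, producing a space-time image (STI): rows are time, columns
are distance along the line.  A feature advected at constant speed traces a
straight streak whose angle theta, measured from the space axis, encodes the
velocity:

    U = (Sx / St) * 1 / tan(theta)

with Sx the length scale of the line (m/pixel) and St the time scale of the
time axis (s/pixel, the frame interval).  A stationary pattern gives streaks
parallel to the time axis (theta -> 90 deg, U -> 0); an infinitely fast one
gives streaks along the space axis (theta -> 0).

theta is estimated from the luminance gradient (structure) tensor: Gaussian
derivative gradients, locally averaged tensor, per-pixel orientation
0.5 * atan2(2<Ix*It>, <Ix^2> - <It^2>) rotated by 90 deg to the streak
direction, accumulated into an anisotropy-weighted orientation histogram whose
refined peak is the reported angle.  Exhaled flow volume follows as V = U * A
(nostril cross-section A) and CO2 output as a fixed fraction of V (4 % of
exhaled breath by volume).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure

from .io_thermal import ThermalStack, TimeSeriesSignal

__all__ = [
    "LineROI",
    "SpaceTimeImage",
    "FlowEstimate",
    "reslice",
    "denoise_sti",
    "enhance_contrast",
    "crop_exhalation",
    "mean_orientation",
    "velocity_from_theta",
    "flow_volume",
    "co2_volume",
    "per_hour",
    "estimate_flow",
]

CO2_EXHALED_FRACTION = 0.04  # CO2 volume fraction of exhaled breath


@dataclass(frozen=True)
class LineROI:
    """A straight sampling line in frame coordinates; sub-pixel endpoints allowed."""

    row0: float
    col0: float
    row1: float
    col1: float

    def __post_init__(self) -> None:
        if self.length_px == 0:
            raise ValueError("line ROI has zero length")

    @property
    def length_px(self) -> float:
        return math.hypot(self.row1 - self.row0, self.col1 - self.col0)

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        for r, c in ((self.row0, self.col0), (self.row1, self.col1)):
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise ValueError(f"line endpoint ({r}, {c}) outside {h}x{w} frame")


@dataclass
class SpaceTimeImage:
    """STI values (n_time x n_space) with axis scales Sx (m/px) and St (s/px)."""

    values: np.ndarray
    sx: float
    st: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("STI must be 2-D (time x space)")
        if not (self.sx > 0 and self.st > 0):
            raise ValueError("Sx and St must be positive")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_space(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FlowEstimate:
    """Velocity and volume-rate estimate for one nostril.

    ``v_m3_per_s`` and ``v_co2_m3_per_s`` are derived properties, so the
    identities V = U * A and V_CO2 = fraction * V hold exactly.
    """

    theta_deg: float
    u_m_per_s: float
    area_m2: float
    co2_fraction: float = CO2_EXHALED_FRACTION
    per_exhalation_theta_deg: tuple = ()
    per_exhalation_u_m_per_s: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.theta_deg < 90:
            raise ValueError("theta must lie strictly inside (0, 90) degrees")
        if not self.u_m_per_s > 0:
            raise ValueError("velocity must be positive")
        if not self.area_m2 > 0:
            raise ValueError("nostril area must be positive")
        if not 0 < self.co2_fraction < 1:
            raise ValueError("CO2 fraction must lie in (0, 1)")

    @property
    def v_m3_per_s(self) -> float:
        return self.u_m_per_s * self.area_m2

    @property
    def v_co2_m3_per_s(self) -> float:
        return self.co2_fraction * self.v_m3_per_s


def reslice(stack: ThermalStack, line: LineROI) -> SpaceTimeImage:
    """Sample the stack along ``line`` at 1-px spacing in every frame.

    Row t of the result is the bilinear intensity profile along the line in
    frame t; ``n_space = floor(length) + 1``.  Sx comes from the stack's pixel
    scale (1.0 with a pixel-units note when uncalibrated), St from 1/fps.
    """
    line.validate_within(stack.frame_shape)
    n = int(math.floor(line.length_px)) + 1
    ur = (line.row1 - line.row0) / line.length_px
    uc = (line.col1 - line.col0) / line.length_px
    steps = np.arange(n)
    rr = line.row0 + steps * ur
    cc = line.col0 + steps * uc

    h, w = stack.frame_shape
    r0 = np.clip(np.floor(rr).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(cc).astype(int), 0, w - 2)
    fr = rr - r0
    fc = cc - c0
    f = stack.frames
    sti = (
        (1 - fr) * (1 - fc) * f[:, r0, c0]
        + fr * (1 - fc) * f[:, r0 + 1, c0]
        + (1 - fr) * fc * f[:, r0, c0 + 1]
        + fr * fc * f[:, r0 + 1, c0 + 1]
    )
    if stack.pixel_scale is None:
        sx, unit_note = 1.0, " (pixel units: Sx=1)"
    else:
        sx, unit_note = stack.pixel_scale, ""
    return SpaceTimeImage(
        values=sti,
        sx=sx,
        st=1.0 / stack.fps,
        provenance=f"resliced {stack.modality} stack along "
        f"({line.row0},{line.col0})->({line.row1},{line.col1}){unit_note}",
    )


def denoise_sti(sti: SpaceTimeImage, window_px: int = 15) -> SpaceTimeImage:
    """1-D median filter along the space axis, row by row (reflected edges)."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("median window must be an odd integer >= 3")
    if window_px > sti.n_space:
        raise ValueError(f"median window {window_px} exceeds STI width {sti.n_space}")
    out = ndi.median_filter(sti.values, size=(1, window_px), mode="reflect")
    return SpaceTimeImage(out, sti.sx, sti.st, sti.provenance + f"; median x{window_px}")


def enhance_contrast(
    sti: SpaceTimeImage,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> SpaceTimeImage:
    """Contrast-limited adaptive histogram equalization, rescaled to [0, 1]."""
    v = sti.values
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant STI: contrast enhancement is a no-op")
        return SpaceTimeImage(v.copy(), sti.sx, sti.st, sti.provenance + "; CLAHE (no-op)")
    norm = (v - lo) / (hi - lo)
    kernel = (
        max(1, int(math.ceil(sti.n_time / tiles[0]))),
        max(1, int(math.ceil(sti.n_space / tiles[1]))),
    )
    out = exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip_limit)
    return SpaceTimeImage(out, sti.sx, sti.st, sti.provenance + "; CLAHE")


def crop_exhalation(
    sti: SpaceTimeImage, windows: list[tuple[float, float]]
) -> list[SpaceTimeImage]:
    """Extract one sub-STI (full space extent) per exhalation window (seconds)."""
    crops = []
    for t0, t1 in windows:
        i0 = int(round(t0 / sti.st))
        i1 = min(int(round(t1 / sti.st)), sti.n_time)
        if not 0 <= i0 < i1:
            raise ValueError(f"empty or out-of-range exhalation window ({t0}, {t1}) s")
        crops.append(
            SpaceTimeImage(
                sti.values[i0:i1].copy(),
                sti.sx,
                sti.st,
                sti.provenance + f"; crop [{t0:.3f},{t1:.3f}]s",
            )
        )
    return crops


def mean_orientation(
    region: SpaceTimeImage,
    gradient_sigma_px: float = 2.0,
    n_bins: int = 90,
) -> float:
    """Dominant streak orientation of an STI region, degrees from the space axis.

    Gradients are Gaussian derivatives at scale ``gradient_sigma_px``; the
    tensor products are averaged at the same scale.  Per-pixel streak
    orientation (gradient direction + 90 deg) is histogrammed over [0, 180)
    weighted by tensor anisotropy (eigenvalue difference); the peak bin is
    refined parabolically and folded into (0, 90).
    """
    v = region.values
    if min(v.shape) < 8:
        raise ValueError(f"region too small for orientation analysis: {v.shape}")
    s = gradient_sigma_px
    it = ndi.gaussian_filter(v, s, order=(1, 0), mode="reflect")
    ix = ndi.gaussian_filter(v, s, order=(0, 1), mode="reflect")
    jxx = ndi.gaussian_filter(ix * ix, s, mode="reflect")
    jxt = ndi.gaussian_filter(ix * it, s, mode="reflect")
    jtt = ndi.gaussian_filter(it * it, s, mode="reflect")

    weight = np.sqrt((jxx - jtt) ** 2 + 4 * jxt**2)  # eigenvalue difference
    scale = float(np.abs(v).max())
    if weight.sum() <= 1e-12 * max(scale, 1.0) ** 2:
        raise ValueError("no oriented gradient energy in region (constant input?)")

    # gradient direction -> streak direction, mod 180 deg
    ori = np.degrees(0.5 * np.arctan2(2 * jxt, jxx - jtt)) + 90.0
    ori %= 180.0

    bin_w = 180.0 / n_bins
    hist, _ = np.histogram(ori, bins=n_bins, range=(0.0, 180.0), weights=weight)
    k = int(np.argmax(hist))
    hm, h0, hp = hist[(k - 1) % n_bins], hist[k], hist[(k + 1) % n_bins]
    denom = hm - 2 * h0 + hp
    delta = 0.5 * (hm - hp) / denom if denom != 0 else 0.0
    theta = ((k + 0.5 + delta) * bin_w) % 180.0
    if theta > 90.0:
        theta = 180.0 - theta
    return float(theta)


def velocity_from_theta(theta_deg: float, sx: float, st: float) -> float:
    """Streak angle to velocity: U = (Sx/St) / tan(theta)."""
    if not 0 < theta_deg < 90:
        raise ValueError(f"theta must lie strictly in (0, 90) deg, got {theta_deg}")
    if not (sx > 0 and st > 0):
        raise ValueError("Sx and St must be positive")
    return (sx / st) / math.tan(math.radians(theta_deg))


def flow_volume(u_m_per_s: float, area_m2: float) -> float:
    """Volume rate through a nostril of cross-section ``area_m2``: V = U * A."""
    if u_m_per_s < 0:
        raise ValueError("velocity must be non-negative")
    if not area_m2 > 0:
        raise ValueError("area must be positive")
    return u_m_per_s * area_m2


def co2_volume(v_m3_per_s: float, fraction: float = CO2_EXHALED_FRACTION) -> float:
    """CO2 volume rate as a fixed fraction of exhaled flow (default 4 %)."""
    if v_m3_per_s < 0:
        raise ValueError("flow rate must be non-negative")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return fraction * v_m3_per_s


def per_hour(rate_m3_per_s: float) -> float:
    """Convert a volume rate from m^3/s to m^3/h."""
    return rate_m3_per_s * 3600.0


def estimate_flow(
    stack: ThermalStack,
    line: LineROI,
    windows: list[tuple[float, float]],
    area_m2: float,
    median_window_px: int = 15,
    clahe_clip: float = 0.01,
    clahe_tiles: tuple[int, int] = (8, 8),
    gradient_sigma_px: float = 2.0,
    n_bins: int = 90,
    co2_fraction: float = CO2_EXHALED_FRACTION,
) -> FlowEstimate:
    """Full STIV chain for one nostril: reslice -> median -> CLAHE -> per-exhalation
    orientation -> velocity, aggregated as the mean across exhalations.

    The per-exhalation angles and velocities are kept on the returned estimate
    because the streak pattern (hence the estimate) is dominated by the early,
    peak-flow phase of each expiration.
    """
    sti = reslice(stack, line)
    sti = denoise_sti(sti, median_window_px)
    sti = enhance_contrast(sti, clip_limit=clahe_clip, tiles=clahe_tiles)
    crops = crop_exhalation(sti, windows)
    thetas, us = [], []
    for crop in crops:
        th = mean_orientation(crop, gradient_sigma_px=gradient_sigma_px, n_bins=n_bins)
        thetas.append(th)
        us.append(velocity_from_theta(th, sti.sx, sti.st))
    if not us:
        raise ValueError("no exhalation windows to analyse")
    u_mean = float(np.mean(us))
    theta_mean = math.degrees(math.atan2(sti.sx / sti.st, u_mean))
    return FlowEstimate(
        theta_deg=theta_mean,
        u_m_per_s=u_mean,
        area_m2=area_m2,
        co2_fraction=co2_fraction,
        per_exhalation_theta_deg=tuple(thetas),
        per_exhalation_u_m_per_s=tuple(us),
    )
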