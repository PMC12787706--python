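"""Exhaled-breath visualization by temporal mean subtraction.

Exhaled air absorbs mid-wave infrared radiation (the ~4.3 um CO2 band), so a
breath plume appears as a faint dark region in front of the face.  Removing
the static scene — subtracting the temporal-mean image from every frame —
leaves only the temporal fluctuations and makes the plume plainly visible,
with no optical bandpass filter or background wall required.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from .io_thermal import ThermalStack

__all__ = ["mean_subtract", "normalize_for_display"]


def mean_subtract(stack: ThermalStack, window: int | None = None) -> ThermalStack:
    """Subtract the temporal mean image from every frame.

    With ``window=None`` (the default, and the fidelity-first choice) the mean
    is global over the whole stack, so the output's temporal mean is exactly
    the zero image and the operation is idempotent.  A sliding-window variant
    (``window`` = odd frame count) subtracts a local temporal mean instead,
    which tolerates slow drift at the cost of those properties.
    """
    if stack.n_frames < 2:
        raise ValueError("mean subtraction needs at least 2 frames")
    if window is None:
        out = stack.frames - stack.frames.mean(axis=0)
        note = "mean-subtracted (global)"
    else:
        if window < 3 or window % 2 == 0:
            raise ValueError("sliding window must be an odd integer >= 3")
        local_mean = ndi.uniform_filter1d(
            stack.frames, size=window, axis=0, mode="nearest"
        )
        out = stack.frames - local_mean
        note = f"mean-subtracted (window {window})"
    return stack.with_frames(out, note=note)


def normalize_for_display(
    stack: ThermalStack, low_pct: float = 1.0, high_pct: float = 99.0
) -> ThermalStack:
    """Map stack values linearly to [0, 1] using global percentiles, clipped.

    Percentiles are computed over the whole stack, not per frame: per-frame
    scaling would rescale away the respiratory contrast between frames.  A
    constant stack maps to 0.5 everywhere by convention.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(stack.frames, [low_pct, high_pct])
    if hi == lo:
        out = np.full_like(stack.frames, 0.5)
    else:
        out = np.clip((stack.frames - lo) / (hi - lo), 0.0, 1.0)
    return stack.with_frames(out, note=f"display-normalized [{low_pct},{high_pct}]%")
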