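"""Brute-force streak-orientation oracle, independent of the structure-tensor path.

For each candidate angle theta (from the space axis) the image is sampled
along a bundle of parallel lines at that angle; if the streaks run at theta,
intensity is constant along each line, so the summed per-line variance is
minimal there.  The score is minimized over a dense angle grid with a final
parabolic refinement.  Only generic interpolation (map_coordinates) is used —
no gradients, no tensors.
"""

import numpy as np
from scipy.ndimage import map_coordinates


def orientation_by_line_scan(
    values: np.ndarray,
    theta_grid_deg: np.ndarray | None = None,
) -> float:
    """Streak angle in degrees from the space (column) axis, in (0, 90)."""
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    if theta_grid_deg is None:
        theta_grid_deg = np.arange(1.0, 89.51, 0.5)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = min(h, w) / (2 * np.sqrt(2)) - 1.0
    u = np.arange(-r, r + 0.5, 1.0)  # along-line coordinate
    off = np.arange(-r, r + 0.5, 1.0)  # across-line offset

    scores = np.empty(theta_grid_deg.size)
    for i, th in enumerate(np.radians(theta_grid_deg)):
        dx, dt = np.cos(th), np.sin(th)  # line direction (x=col, t=row)
        nx, nt = -np.sin(th), np.cos(th)  # normal
        cols = cx + u[None, :] * dx + off[:, None] * nx
        rows = cy + u[None, :] * dt + off[:, None] * nt
        profiles = map_coordinates(
            values, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(off.size, u.size)
        scores[i] = profiles.var(axis=1).mean()

    k = int(np.argmin(scores))
    if 0 < k < scores.size - 1:
        denom = scores[k - 1] - 2 * scores[k] + scores[k + 1]
        delta = 0.5 * (scores[k - 1] - scores[k + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    step = theta_grid_deg[1] - theta_grid_deg[0]
    return float(theta_grid_deg[k] + delta * step)
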