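"""Containers and file I/O for thermal recordings and 1-D physiological signals.

A recording is a ``ThermalStack``: a T x H x W array of temperatures (deg C) or
arbitrary intensities together with its frame rate, optional spatial
calibration (metres per pixel, needed for velocimetry) and a modality tag
(MWIR / LWIR / SYNTHETIC).  Stacks travel on disk as multi-page float32 TIFFs
with a JSON sidecar holding the metadata; integer TIFFs are supported through
a linear gain/offset calibration.  One-dimensional signals (ROI traces, PPG)
are ``TimeSeriesSignal`` objects stored as single-column CSV files.

Conventions used throughout the package: pixel coordinates are 0-based
``(row, col)`` with row 0 at the top of the image, and all pixel ranges are
half-open ``[start, end)``.  Frame-per-file directories are read in
lexicographic order, so frame indices must be zero-padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

MODALITIES = ("MWIR", "LWIR", "SYNTHETIC")

__all__ = [
    "ThermalStack",
    "TimeSeriesSignal",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_signal_csv",
    "write_signal_csv",
    "sidecar_path",
]


@dataclass
class ThermalStack:
    """A thermal video: frames indexed (time, row, col) plus acquisition metadata.

    Parameters
    ----------
    frames
        T x H x W real-valued array (deg C for calibrated recordings).
    fps
        Acquisition frame rate in frames per second (> 0).
    pixel_scale
        Physical length of one pixel in metres, if known.  Required only for
        velocimetry; ROI statistics and rate estimation work without it.
    modality
        One of ``"MWIR"``, ``"LWIR"``, ``"SYNTHETIC"``.
    origin_note
        Free-text provenance (source file, processing applied, ...).
    """

    frames: np.ndarray
    fps: float
    pixel_scale: float | None = None
    modality: str = "SYNTHETIC"
    origin_note: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if min(self.frames.shape) < 1:
            raise ValueError(f"empty stack dimension: shape {self.frames.shape}")
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite pixel values")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.pixel_scale is not None and not self.pixel_scale > 0:
            raise ValueError(f"pixel_scale must be positive, got {self.pixel_scale}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.fps

    def with_frames(self, frames: np.ndarray, note: str = "") -> "ThermalStack":
        """Copy of this stack with new pixel data; metadata preserved."""
        out = replace(self, frames=frames)
        if note:
            out.origin_note = (self.origin_note + "; " + note).lstrip("; ")
        return out


@dataclass
class TimeSeriesSignal:
    """A uniformly sampled 1-D signal (ROI trace, filtered trace, PPG)."""

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar that accompanies a TIFF stack (``stack.tiff`` -> ``stack.json``)."""
    return Path(path).with_suffix(".json")


def _read_frames(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF frames in directory {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        return np.stack(frames, axis=0)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF data, got shape {arr.shape}")
    return arr


def read_tiff_stack(
    path: str | Path,
    fps: float | None = None,
    pixel_scale: float | None = None,
    modality: str | None = None,
    gain: float | None = None,
    offset: float | None = None,
) -> ThermalStack:
    """Read a thermal stack from a multi-page TIFF or a directory of frames.

    Metadata defaults come from the JSON sidecar when present; explicit
    arguments override it.  Integer pixel encodings are converted to real
    values by the linear calibration ``value = gain * raw + offset``
    (defaults gain 1, offset 0, i.e. identity for pre-calibrated exports).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.is_file():
        meta = json.loads(sc.read_text())
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        raise ValueError(f"fps not given and no sidecar metadata found for {path}")
    if pixel_scale is None:
        pixel_scale = meta.get("pixel_scale_m_per_px")
    if modality is None:
        modality = meta.get("modality", "SYNTHETIC")
    if gain is None:
        gain = meta.get("gain", 1.0)
    if offset is None:
        offset = meta.get("offset", 0.0)

    raw = _read_frames(path)
    if not np.issubdtype(raw.dtype, np.number):
        raise ValueError(f"non-numeric pixel data ({raw.dtype}) in {path}")
    if np.issubdtype(raw.dtype, np.integer):
        frames = gain * raw.astype(np.float64) + offset
    else:
        frames = raw if (gain == 1.0 and offset == 0.0) else gain * raw + offset
    return ThermalStack(
        frames=frames,
        fps=float(fps),
        pixel_scale=pixel_scale,
        modality=modality,
        origin_note=f"read from {path.name}",
    )


def write_tiff_stack(stack: ThermalStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "fps": stack.fps,
        "pixel_scale_m_per_px": stack.pixel_scale,
        "modality": stack.modality,
        "gain": 1.0,
        "offset": 0.0,
        "origin_note": stack.origin_note,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_signal_csv(path: str | Path, fs: float, label: str = "") -> TimeSeriesSignal:
    """Read a one-column CSV of samples; a single non-numeric header line is skipped."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            token = line.strip().rstrip(",")
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                if i == 0 and not values:
                    continue  # header
                raise ValueError(f"non-numeric row {i + 1} in {path}: {line.strip()!r}")
    if len(values) < 2:
        raise ValueError(f"fewer than 2 samples in {path}")
    return TimeSeriesSignal(np.asarray(values), fs=fs, label=label or path.stem)


def write_signal_csv(signal: TimeSeriesSignal, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = signal.label or "value"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in signal.values:
            fh.write(f"{v:.17g}\n")
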