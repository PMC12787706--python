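"""End-to-end composition: phantom (or files) -> visualization -> rates ->
thermometry -> heart rate -> STIV flow, collected into one JSON-able report.

``RunConfig`` is a plain dataclass loadable from YAML; every field it carries
is echoed into the report so a run is reproducible from the report alone.
All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .agreement import bland_altman
from .breath_viz import mean_subtract
from .io_thermal import (
    ThermalStack,
    read_signal_csv,
    read_tiff_stack,
    write_signal_csv,
    write_tiff_stack,
)
from .signals import (
    PULSE_BAND_HZ,
    RESPIRATION_BAND_HZ,
    RectROI,
    average_bilateral,
    estimate_rate,
    extract_roi_signal,
    invert,
)
from .stiv import LineROI, estimate_flow, per_hour
from .synthetic import (
    GroundTruth,
    PhantomConfig,
    default_resp_roi,
    default_stiv_line,
    generate_lwir_phantom,
    generate_mwir_phantom,
    generate_ppg,
)
from .temperature import body_temperature, heart_rate, segment_hottest, temporal_mean_image

__all__ = ["RunConfig", "run_pipeline", "simulate"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; phantom mode when ``phantom`` is set."""

    outdir: str = "thermovitals_run"
    seed: int = 0
    phantom: dict | None = None  # PhantomConfig field overrides
    mwir_path: str | None = None
    resp_roi: tuple | None = None  # (row0, col0, row1, col1)
    resp_band_hz: tuple = RESPIRATION_BAND_HZ
    pulse_band_hz: tuple = PULSE_BAND_HZ
    temp_threshold_c: float | None = None
    temp_percentile: float = 99.5
    stiv_line: tuple | None = None  # (row0, col0, row1, col1)
    stiv_windows: list | None = None  # [(t0, t1), ...] seconds
    stiv_median_px: int = 15
    stiv_clahe_clip: float = 0.01
    area_right_m2: float = 7.18e-5
    co2_fraction: float = 0.04
    reference_csv: str | None = None  # paired reference for agreement
    method_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def simulate(config: PhantomConfig, outdir: str | Path) -> dict:
    """Write the full phantom file set (MWIR/LWIR stacks, PPG CSV, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mwir, truth = generate_mwir_phantom(config)
    lwir, _ = generate_lwir_phantom(config)
    ppg = generate_ppg(config)
    write_tiff_stack(mwir, outdir / "mwir.tiff")
    write_tiff_stack(lwir, outdir / "lwir.tiff")
    write_signal_csv(ppg, outdir / "ppg.csv")
    truth.to_json(outdir / "ground_truth.json")
    (outdir / "phantom_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config))
    )
    return {
        "mwir": str(outdir / "mwir.tiff"),
        "lwir": str(outdir / "lwir.tiff"),
        "ppg": str(outdir / "ppg.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software_version": __version__,
        "config": dataclasses.asdict(config),
    }

    truth: GroundTruth | None = None
    if config.phantom is not None:
        pc = PhantomConfig(**{**config.phantom, "seed": config.seed})
        stack, truth = generate_mwir_phantom(pc)
        resp_roi = (
            RectROI(*config.resp_roi) if config.resp_roi else default_resp_roi(pc)
        )
        line = LineROI(*config.stiv_line) if config.stiv_line else default_stiv_line(pc)
        windows = config.stiv_windows or truth.exhalation_windows
        report["phantom_ground_truth"] = dataclasses.asdict(truth)
    elif config.mwir_path is not None:
        stack = read_tiff_stack(config.mwir_path)
        if config.resp_roi is None:
            raise ValueError("resp_roi is required when reading a recorded stack")
        resp_roi = RectROI(*config.resp_roi)
        line = LineROI(*config.stiv_line) if config.stiv_line else None
        windows = config.stiv_windows
    else:
        raise ValueError("config must set either 'phantom' or 'mwir_path'")

    # --- visualization + respiration ---------------------------------------
    viz = mean_subtract(stack)
    resp_sig = invert(extract_roi_signal(viz, resp_roi))
    td = estimate_rate(resp_sig, config.resp_band_hz, method="time_domain")
    fd = estimate_rate(resp_sig, config.resp_band_hz, method="frequency_domain")
    report["respiration"] = {
        "roi": dataclasses.astuple(resp_roi),
        "band_hz": list(config.resp_band_hz),
        "rate_td_bpm": td.rate_bpm,
        "rate_fd_bpm": fd.rate_bpm,
        "n_peaks": int(td.peak_indices.size),
    }

    # --- thermometry + heart rate ------------------------------------------
    mean_img = temporal_mean_image(stack)
    mask = segment_hottest(
        mean_img,
        threshold_c=config.temp_threshold_c,
        percentile=config.temp_percentile,
    )
    hr = heart_rate(stack, mask, band_hz=config.pulse_band_hz)
    report["temperature"] = {
        "threshold": mask.source_threshold,
        "mask_pixels": mask.n_pixels,
        "components": mask.component_count,
        "body_temperature_c": body_temperature(stack, mask),
    }
    report["heart_rate"] = {
        "band_hz": list(config.pulse_band_hz),
        "rate_td_bpm": hr.rate_bpm,
    }

    # --- STIV flow ----------------------------------------------------------
    if line is not None and windows:
        if stack.pixel_scale is None:
            raise ValueError("pixel_scale required for STIV velocity estimation")
        flow = estimate_flow(
            viz,
            line,
            windows,
            area_m2=config.area_right_m2,
            median_window_px=config.stiv_median_px,
            clahe_clip=config.stiv_clahe_clip,
            co2_fraction=config.co2_fraction,
        )
        report["stiv"] = {
            "line": (line.row0, line.col0, line.row1, line.col1),
            "theta_deg": flow.theta_deg,
            "u_m_per_s": flow.u_m_per_s,
            "area_m2": flow.area_m2,
            "v_m3_per_s": flow.v_m3_per_s,
            "v_co2_m3_per_s": flow.v_co2_m3_per_s,
            "v_co2_m3_per_h": per_hour(flow.v_co2_m3_per_s),
            "per_exhalation_u_m_per_s": list(flow.per_exhalation_u_m_per_s),
        }

    # --- agreement against a supplied reference -----------------------------
    if config.method_csv and config.reference_csv:
        m = read_signal_csv(config.method_csv, fs=1.0).values
        r = read_signal_csv(config.reference_csv, fs=1.0).values
        report["agreement"] = bland_altman(m, r).to_dict()

    config.to_yaml(outdir / "config_effective.yaml")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
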