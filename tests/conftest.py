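import numpy as np
import pytest

from thermovitals import PhantomConfig, ThermalStack


@pytest.fixture
def small_cfg() -> PhantomConfig:
    """A fast 20-s phantom on a 64x56 frame; geometry scaled to the small field."""
    return PhantomConfig(
        duration_s=20.0,
        fps=60.0,
        height_px=64,
        width_px=56,
        canthus_centres=((18, 20), (18, 36)),
        nostril_centres=((30, 24), (30, 32)),
        seed=7,
    )


@pytest.fixture
def stiv_cfg() -> PhantomConfig:
    """Phantom tuned for velocimetry: short expirations so a puff fits the frame."""
    return PhantomConfig(
        duration_s=20.0,
        fps=60.0,
        height_px=96,
        width_px=80,
        resp_rate_bpm=15.0,
        exhale_fraction=0.25,
        pixel_scale_m_per_px=0.03125,
        plume_velocity_m_per_s=1.0,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def make_stack(frames, fps=60.0, **kw) -> ThermalStack:
    return ThermalStack(frames=np.asarray(frames, dtype=float), fps=fps, **kw)
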