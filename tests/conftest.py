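import numpy as np
import pytest

from mtdynamics import DIParams, ImagingParams, LengthTrace


@pytest.fixture
def wildtype_invivo_params() -> DIParams:
    """Wild-type-like astral microtubule kinetics (rates in μm/min)."""
    return DIParams(
        v_grow=26.5 * 60 / 1000,
        v_shrink=46.7 * 60 / 1000,
        f_cat=0.0167 * 60,
        f_res=0.0278 * 60,
        seed_length_um=0.0,
    )


@pytest.fixture
def clean_imaging() -> ImagingParams:
    return ImagingParams(
        pixel_size_nm=65.0,
        frame_interval_s=3.0,
        psf_sigma_nm=130.0,
        tip_sd_nm=0.0,
        noise_model="none",
        background_level=5.0,
    )


def make_trace(lengths_um, dt_s=1.0) -> LengthTrace:
    lengths_um = np.asarray(lengths_um, dtype=float)
    return LengthTrace(
        times_s=np.arange(lengths_um.size) * dt_s,
        lengths_um=lengths_um,
        frame_interval_s=dt_s,
    )
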