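import dataclasses

import pytest

from celltribo.synthetic import ImageScenario, TraceScenario


@pytest.fixture
def clean_trace_scenario():
    """Noise-free, stick-slip-free slide on a tilted plane (no meniscus)."""
    return TraceScenario(
        mu_s=0.1,
        mu_d=0.05,
        f_n=10.0,
        tilt=0.02,
        meniscus_depth=0.0,
        stickslip_amp=0.0,
        noise_sd_f=0.0,
        noise_sd_h=0.0,
        fx_baseline=0.05,
        seed=0,
    )


@pytest.fixture
def small_image_scenario():
    """Compact field of view for fast detection tests (0.6 x 0.8 mm)."""
    return ImageScenario(
        density_ref=400.0,
        track_width=100.0,
        p_remove=0.8,
        p_dead=0.5,
        image_size=(300, 400),
        pixel_size=2.0,
        seed=0,
    )


def replace(obj, **kwargs):
    return dataclasses.replace(obj, **kwargs)
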