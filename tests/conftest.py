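import numpy as np
import pytest

from fmibench import (
    IntensityImage,
    SyntheticConfig,
    default_template,
    render_default,
)


@pytest.fixture(scope="session")
def tmpl():
    return default_template()


@pytest.fixture(scope="session")
def noiseless_cfg():
    """High-signal noise-free configuration: every downstream stage has an
    analytically known answer."""
    return SyntheticConfig(
        image_shape=(200, 260),
        bit_depth=16,
        background_level=100.0,
        peak_amplitude=20000.0,
        attenuation_mu=0.6,
        blur_sigma0=1.0,
        blur_slope=0.5,
        poisson_gain=0.0,
        read_noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_cfg):
    image, truth, t = render_default(noiseless_cfg)
    return image, truth, t


@pytest.fixture(scope="session")
def noiseless_image(noiseless_phantom, noiseless_cfg):
    image, _, _ = noiseless_phantom
    return IntensityImage(
        values=image, bit_depth=noiseless_cfg.bit_depth, source_id="noiseless"
    )


@pytest.fixture(scope="session")
def shallow_phantom():
    """Noise-free phantom with weak attenuation: all nine wells stay far
    above any global threshold, so detection must find every one."""
    cfg = SyntheticConfig(
        image_shape=(200, 260),
        bit_depth=16,
        background_level=100.0,
        peak_amplitude=20000.0,
        attenuation_mu=0.15,
        blur_sigma0=0.8,
        blur_slope=0.2,
        poisson_gain=0.0,
        read_noise_sigma=0.0,
        seed=7,
    )
    return render_default(cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    return SyntheticConfig(
        image_shape=(200, 260),
        bit_depth=16,
        background_level=200.0,
        peak_amplitude=15000.0,
        attenuation_mu=0.7,
        blur_sigma0=1.0,
        blur_slope=0.8,
        poisson_gain=1.0,
        read_noise_sigma=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_phantom(noisy_cfg):
    image, truth, t = render_default(noisy_cfg)
    return image, truth, t


@pytest.fixture(scope="session")
def noisy_image(noisy_phantom, noisy_cfg):
    image, _, _ = noisy_phantom
    return IntensityImage(
        values=image, bit_depth=noisy_cfg.bit_depth, source_id="noisy"
    )


def make_stats(mean=0.0, std=1.0, min_=None, max_=None, count=100):
    """RegionStats with just the fields a formula needs."""
    from fmibench import RegionStats

    lo = mean if min_ is None else min_
    hi = mean if max_ is None else max_
    return RegionStats(
        mean=mean, std=std, min=min(lo, mean), max=max(hi, mean), count=count
    )
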