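import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from duobeam import RunConfig
from duobeam.synth import CameraModel, SceneConfig, render

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def anchored_config(gt, **overrides) -> RunConfig:
    """RunConfig whose LED anchors are the generator's true peak wavelengths.

    Mirrors the bench procedure: the anchor wavelengths are measured once
    per LED with a reference spectrometer, then reused for every frame.
    """
    kwargs = dict(lambda_red_nm=gt.lambda_red, lambda_blue_nm=gt.lambda_blue)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def default_anchors():
    """True anchor wavelengths of the default LED/camera, from a clean render."""
    _, gt = render(SceneConfig(), camera=CameraModel(noise_sd=0.0), seed=0)
    return gt.lambda_red, gt.lambda_blue


@pytest.fixture
def anchored(default_anchors):
    lam_red, lam_blue = default_anchors

    def make(**overrides) -> RunConfig:
        kwargs = dict(lambda_red_nm=lam_red, lambda_blue_nm=lam_blue)
        kwargs.update(overrides)
        return RunConfig(**kwargs)

    return make


def region_iou(region, mask: np.ndarray) -> float:
    box = region.mask(*mask.shape)
    return (box & mask).sum() / (box | mask).sum()
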