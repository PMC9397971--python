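import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "mubkit",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mubkit")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_longitudinal():
    """Noise-free longitudinal render with a flat 5.15 mm band."""
    from mubkit.synthetic import TendonImageParams, render_tendon_image

    params = TendonImageParams(thickness_mm=5.15, mean_echo=77.0,
                               fibril_contrast=0.0, speckle_scale=0.0)
    image, boundaries = render_tendon_image(params, 400, 400, rng_seed=0)
    return params, image, boundaries


def make_image(pixels, row_spacing_mm=0.05, col_spacing_mm=0.1,
               plane="longitudinal", **kw):
    from mubkit.geometry import CalibratedImage

    return CalibratedImage(pixels=np.asarray(pixels, dtype=np.uint8),
                           row_spacing_mm=row_spacing_mm,
                           col_spacing_mm=col_spacing_mm, plane=plane, **kw)


def rect_polygon(r0, r1, c0, c1):
    """Axis-aligned rectangle polygon with corners on the given coords."""
    return [(r0, c0), (r0, c1), (r1, c1), (r1, c0)]
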