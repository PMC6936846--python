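import numpy as np
import pytest

from octshape import (
    REGIONS,
    ContourShapeTransformer,
    ScanSpec,
    SynthConfig,
    synth_cohort,
)

SMALL_REGIONS = ("macula", "posterior inferior", "anterior nasal")


@pytest.fixture(scope="session")
def spec() -> ScanSpec:
    return ScanSpec()


@pytest.fixture(scope="session")
def small_synth():
    """A small but structurally complete synthetic cohort."""
    cfg = SynthConfig(n_eyes=12, regions=SMALL_REGIONS, scans_per_cube=7,
                      seed=42)
    return synth_cohort(cfg)


@pytest.fixture(scope="session")
def small_descriptors(small_synth):
    return ContourShapeTransformer().fit(None).transform(
        small_synth.cohort.contours)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_parabola_contour(a=0.013, b=0.0, c=1.0, n=1024, spec=None, **kw):
    """Noise-free parabola sampled on the pixel grid, as a contour."""
    from octshape import BScanContour, EyeRecord

    spec = spec or ScanSpec()
    x = np.arange(n) * spec.dx_mm
    z = a * x**2 + b * x + c
    eye = kw.pop("eye", EyeRecord(eye_id="e0", axial_length_mm=24.0))
    return BScanContour(eye=eye, region=kw.pop("region", "macula"),
                        cube_id=kw.pop("cube_id", "c0"),
                        scan_index=kw.pop("scan_index", 0),
                        x_mm=x, z_mm=z, dx_mm=spec.dx_mm)
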