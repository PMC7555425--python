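import numpy as np
import pytest

import segqc
from segqc.metrics import metric_panel
from segqc.phantom import PerturbationSpec, generate_observer_cohort


@pytest.fixture(scope="session")
def phantom_case():
    """One default 64^3 phantom: (image, gold mask)."""
    return segqc.generate_phantom(segqc.PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom_case():
    """A 40^3 phantom for faster feature-extraction tests."""
    spec = segqc.PhantomSpec(
        grid_shape=(40, 40, 40),
        ellipsoid_center=(20.0, 20.0, 20.0),
        ellipsoid_radii=(12.0, 14.0, 13.0),
    )
    return segqc.generate_phantom(spec)


@pytest.fixture(scope="session")
def calibration():
    """Calibration fitted on a small synthetic observer cohort."""
    cases = generate_observer_cohort(
        12,
        segqc.PhantomSpec(),
        PerturbationSpec("boundary_jitter", 1.0),
        seed=42,
    )
    panels = [metric_panel(c.observer, c.gold) for c in cases]
    return segqc.fit_calibration(panels)


def block_mask(shape, slices, spacing=(1.0, 1.0, 1.0)):
    """A rectangular block mask helper."""
    vox = np.zeros(shape, dtype=np.uint8)
    vox[slices] = 1
    return segqc.SegMask(vox, spacing)
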