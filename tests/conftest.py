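import warnings

import numpy as np
import pytest

from echoquant.phantom import PhantomSpec, generate_geometry


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Quantification on partial inputs warns by design; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def a2c_spec():
    return PhantomSpec(patient_id="T", view="A2C", image_size=256)


@pytest.fixture(scope="session")
def truth_mask_set():
    """ED/ES masks of all three views for one default phantom at 256 px."""
    kwargs = dict(image_size=256, nominal_edv=120.0, nominal_esv=48.0, wall_thickness=10.0)
    masks = {}
    for view in ("A2C", "A4C"):
        spec = PhantomSpec(view=view, **kwargs)
        masks[(view, "ED")] = generate_geometry(spec, 0.0)
        masks[(view, "ES")] = generate_geometry(spec, 0.5)
    psax = PhantomSpec(view="PSAX", **kwargs)
    masks[("PSAX", "ED")] = generate_geometry(psax, 0.0)
    return masks, PhantomSpec(view="A2C", **kwargs)
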