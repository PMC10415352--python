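import numpy as np
import pytest

from oscmem import defaults
from oscmem.analysis import (level_spacing_s, staircase, tune_linear_autapse,
                             wb_autapse_model)


@pytest.fixture(scope="session")
def autapse():
    """Calibrated oscillatory W-B autapse: (params, model, w, drive)."""
    params = dict(defaults.WB_AUTAPSE)
    model, w, drive = wb_autapse_model(params)
    return params, model, w, drive


@pytest.fixture(scope="session")
def level_ds(autapse):
    _, model, _, drive = autapse
    return level_spacing_s(model.syn, drive.omega)


@pytest.fixture(scope="session")
def calibrated_staircase(autapse, level_ds):
    """Clamped-feedback staircase over the calibrated memory range."""
    params, model, w, drive = autapse
    s_grid = np.linspace(0.0, (params["levels"] + 0.5) * level_ds, 30)
    return staircase(model, w, drive, s_grid, cycles_per_point=12)


@pytest.fixture(scope="session")
def tuned_surrogate():
    """Marginally tuned linear spiking integrator parameters."""
    return tune_linear_autapse()
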