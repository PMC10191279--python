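import numpy as np
import pytest
from hypothesis import settings

import nanopbpk as nb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse():
    return nb.load_species("mouse")


@pytest.fixture(scope="session")
def rat():
    return nb.load_species("rat")


@pytest.fixture(scope="session")
def dog():
    return nb.load_species("dog")


@pytest.fixture(scope="session")
def human():
    return nb.load_species("human")


@pytest.fixture(scope="session")
def mouse_bolus():
    return nb.DoseRegimen(10.0, "bolus")


@pytest.fixture(scope="session")
def mouse_course(mouse, mouse_bolus):
    """Nominal mouse simulation (CL = 1 L/h/kg, 10 mg/kg IV bolus)."""
    return nb.simulate(
        mouse.physiology, mouse.released, mouse.conjugated, mouse_bolus
    )


@pytest.fixture(scope="session")
def dog_oat(dog):
    """Dog one-at-a-time sensitivity results for all recognised parameters."""
    from nanopbpk.pipeline import default_regimen
    from nanopbpk.sensitivity import SENSITIVITY_PARAMETERS, oat_sensitivity

    regimen = default_regimen("dog")
    return {
        p: oat_sensitivity(
            dog.physiology, dog.released, dog.conjugated, regimen, p
        )
        for p in SENSITIVITY_PARAMETERS
    }


@pytest.fixture(scope="session")
def schedule_course():
    """Simulate a species at a plasma sampling schedule (plus t = 0)."""
    from nanopbpk.pipeline import default_regimen

    def _run(bundle, schedule):
        grid = np.unique(np.concatenate([[0.0], np.asarray(schedule, dtype=float)]))
        return nb.simulate(
            bundle.physiology,
            bundle.released,
            bundle.conjugated,
            default_regimen(bundle.name),
            times=grid,
        )

    return _run
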