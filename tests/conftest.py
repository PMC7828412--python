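import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from thermosol import TemperatureSeries, VantHoffParams, eval_vanthoff
from thermosol import refdata

STUDY_TEMPERATURES = np.array([298.15, 303.15, 308.15, 313.15, 318.15])


@pytest.fixture(scope="session")
def study_temps():
    return STUDY_TEMPERATURES.copy()


@pytest.fixture(scope="session")
def water_vanthoff():
    """Published van't Hoff parameters for ABN401 in water."""
    return refdata.vanthoff_params("water")


@pytest.fixture(scope="session")
def fusion():
    """Published ABN401 fusion properties (Tfus 413.09 K, ΔHfus 20.32 kJ/mol)."""
    return refdata.fusion_properties()


def vanthoff_series(params: VantHoffParams, temps=STUDY_TEMPERATURES,
                    solvent_id="fixture") -> TemperatureSeries:
    """Noiseless series generated from a van't Hoff line."""
    x = np.exp(eval_vanthoff(params, temps))
    return TemperatureSeries(solvent_id=solvent_id, temperatures=temps, x=x)
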