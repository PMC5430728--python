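import numpy as np
import pandas as pd
import pytest

from phenotensor import EventTable
from phenotensor.synthetic import PlantSpec, simulate


@pytest.fixture
def tiny_events() -> EventTable:
    """One patient, two diagnoses, one prescription (ordered once each)."""
    rows = pd.DataFrame(
        {
            "patient_id": ["p1"] * 3,
            "admission_id": ["a1"] * 3,
            "timestamp": [1, 2, 3],
            "code": ["resp_failure", "hypertension", "phenylephrine"],
            "modality": ["diagnosis", "diagnosis", "prescription"],
        }
    )
    return EventTable(events=rows, outcome={"p1": -1})


def small_spec(seed: int = 7, noise: bool = True) -> PlantSpec:
    return PlantSpec(I=60, J=18, K=24, R_true=3, seed=seed, noise=noise,
                     lam_true=np.full(3, 150.0))


@pytest.fixture(scope="session")
def small_world() -> dict:
    """Desk-scale planted world: 60 patients, 3 phenotypes, Poisson counts."""
    return simulate(small_spec())


@pytest.fixture(scope="session")
def default_world() -> dict:
    """The generator's default planted world (400 patients, 6 phenotypes)."""
    return simulate(PlantSpec(seed=1))
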