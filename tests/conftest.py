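import numpy as np
import pytest

from oncophylo.records import DiagnosisDictionary, NameMap, NecropsyRecord
from oncophylo.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def toy_dictionary() -> DiagnosisDictionary:
    return DiagnosisDictionary(
        {
            "adenoma": "benign",
            "fibroma": "benign",
            "lymphoma": "malignant",
            "carcinoma": "malignant",
            "hyperplasia": "non_neoplastic",
        }
    )


@pytest.fixture(scope="session")
def toy_name_map() -> NameMap:
    return NameMap(
        {
            "domestic ferret": "Mustela putorius",
            "virginia opossum": "Didelphis virginiana",
            "african pygmy hedgehog": "Atelerix albiventris",
        }
    )


def make_record(i, common="domestic ferret", terms=(), clade="Mammalia", **kw):
    defaults = dict(
        record_id=f"R{i:04d}",
        institution="Zoo_01",
        common_name=common,
        clade=clade,
        diagnosis_terms=tuple(terms),
    )
    defaults.update(kw)
    return NecropsyRecord(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """A complete 30-species synthetic study bundle (fixed seed)."""
    return simulate_study(SimulationConfig(seed=42, n_species=30))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
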