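import numpy as np
import pytest
from hypothesis import settings

from repairmut.episome import default_lesion_catalog, default_reference
from repairmut.reference import ReporterReference
from repairmut.simulate import SimParams, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference() -> ReporterReference:
    return default_reference()


@pytest.fixture(scope="session")
def catalog():
    return default_lesion_catalog()


@pytest.fixture(scope="session")
def params() -> SimParams:
    return SimParams(seed=1)


@pytest.fixture(scope="session")
def small_dataset(reference, catalog, params):
    """A modest simulated experiment shared across analysis tests."""
    return simulate_experiment(
        ["UG_top", "TG_top", "noMM"],
        catalog,
        reference,
        params,
        n_transfections=2,
        n_colonies=20_000,
    )


def toy_reference(seq: str, name: str = "toy") -> ReporterReference:
    """Minimal valid reference wrapping an arbitrary short sequence."""
    assert len(seq) >= 4
    return ReporterReference(
        name=name,
        top_sequence=seq,
        regions={
            "promoter": (0, 1),
            "supf": (1, 2),
            "mm_region": (2, 3),
            "barcode": (3, 4),
            "backbone": (0, len(seq)),
        },
    )
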