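"""Shared fixtures: synthetic protomers analysed once per session."""

import pytest

from bcoi.filters import run_filter_suite
from bcoi.pipeline import analyse_protomer
from bcoi.synthetic import (
    BuriedCluster,
    RotamerGate,
    SurfaceSingleton,
    ToyProtomerSpec,
    make_toy_protomer,
)

FULL_FEATURES = (
    BuriedCluster(("ASP", "LYS", "ASP"), distance=4.0),     # buried triad
    SurfaceSingleton("LYS"),                                # exposed singleton
    RotamerGate("LYS", open_rotamers=(120.0,)),             # one open rotamer
    RotamerGate("LYS", open_rotamers=()),                   # fully enclosed
    BuriedCluster(("ASP", "HIS"), distance=4.0),            # compensated pair
)


@pytest.fixture(scope="session")
def toy_full():
    """One protomer carrying every planted feature type."""
    return make_toy_protomer(ToyProtomerSpec(protein_id="toyfull",
                                             features=FULL_FEATURES))


@pytest.fixture(scope="session")
def toy_outputs(toy_full):
    return analyse_protomer(toy_full.model)


@pytest.fixture(scope="session")
def toy_result(toy_outputs):
    return run_filter_suite(toy_outputs)


@pytest.fixture(scope="session")
def surface_triad_result():
    toy = make_toy_protomer(ToyProtomerSpec(
        protein_id="surftriad",
        features=(BuriedCluster(("ASP", "LYS", "ASP"), caged=False),)))
    return run_filter_suite(analyse_protomer(toy.model))
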