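import numpy as np
import pytest

from robfold import FamilySpec, MotifPattern, generate_family


@pytest.fixture(scope="session")
def cxxc() -> MotifPattern:
    return MotifPattern(name="CXXC", regex="C..C")


@pytest.fixture(scope="session")
def pdi_like():
    """Disulfide-isomerase-like synthetic family: 11 proteins, two CGHC
    anchors each, conserved 20-residue core, variable flanks."""
    spec = FamilySpec(seed=7)
    records, truth = generate_family(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def hsp70_like():
    """Chaperone-like synthetic family: 7 proteins, one EEVD anchor each,
    planted triple-helix layout."""
    spec = FamilySpec(
        n_proteins=7,
        length=450,
        motif="EEVD",
        search_pattern="EEVD",
        anchors_per_protein=1,
        layout=(("H", 10), ("C", 4), ("H", 10), ("C", 4), ("H", 10)),
        seed=11,
        id_prefix="HSP",
    )
    records, truth = generate_family(spec)
    return spec, records, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
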