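import pytest

from meltdiag import (
    BarcodeSpec,
    ThermoConditions,
    classify_sites,
    collapse_haplotypes,
    make_minibarcode_alignment,
)


@pytest.fixture(scope="session")
def default_alignment():
    """Default two-species mini-barcode alignment (60 bp, 4 fixed + 4 shared
    third-position transitions, 43 + 22 specimens, 3 haplotypes/species)."""
    return make_minibarcode_alignment(BarcodeSpec(seed=1))


@pytest.fixture(scope="session")
def default_sites(default_alignment):
    return classify_sites(default_alignment)


@pytest.fixture(scope="session")
def default_haplotypes(default_alignment):
    return collapse_haplotypes(default_alignment)


@pytest.fixture(scope="session")
def cond():
    return ThermoConditions()


@pytest.fixture(scope="session")
def species_labels(default_alignment):
    return default_alignment.species_labels
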