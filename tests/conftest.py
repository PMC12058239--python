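import numpy as np
import pytest

from augscreen.assay_analysis import load_atpase_reference_table
from augscreen.chem_core import Molecule, read_molecule_table
from augscreen.synthetic_data import ChemotypeSpec, make_chemotype_family

from importlib import resources


@pytest.fixture(scope="session")
def ten_compounds() -> list[Molecule]:
    with resources.as_file(resources.files("augscreen.data").joinpath("ten_compounds.smi")) as p:
        return read_molecule_table(p, source="fixture")


@pytest.fixture(scope="session")
def atpase_table():
    return load_atpase_reference_table()


@pytest.fixture(scope="session")
def family() -> list[Molecule]:
    """Default synthetic activator-chemotype family (deterministic)."""
    return make_chemotype_family(ChemotypeSpec(rng_seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
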