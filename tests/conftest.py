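import warnings

import numpy as np
import pytest
from rdkit import Chem

from pharmqsar import MoleculeRecord, generate_conformers
from pharmqsar.pharmacophore import ensemble_features
from pharmqsar.pipeline import run_synthetic_study
from pharmqsar.synthlib import SyntheticLibrarySpec

SCAFFOLD_SMILES = "O=C(c1ccccc1)Nc1ccccc1N"  # N-(2-aminophenyl)benzamide


@pytest.fixture(scope="session")
def scaffold_ensemble():
    rec = MoleculeRecord(id="scaffold", mol=Chem.MolFromSmiles(SCAFFOLD_SMILES))
    return generate_conformers(rec, max_confs=10, seed=5)


@pytest.fixture(scope="session")
def scaffold_features(scaffold_ensemble):
    return ensemble_features(scaffold_ensemble)


@pytest.fixture(scope="session")
def small_study():
    """One reduced synthetic study shared by the slower model-level tests."""
    spec = SyntheticLibrarySpec(
        n_actives=15, n_moderate=40, n_inactive=25, n_decoys_per_active=15, seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic_study(
            seed=7, spec=spec, n_pharm_actives=12, n_pharm_inactives=12, hit_count=10
        )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
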