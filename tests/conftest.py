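import numpy as np
import pandas as pd
import pytest

from proteomicelle import (
    AnnotatedEnsemble,
    MicelleSimSpec,
    gen_bundle,
    gen_proteomicelle,
    load_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def bundle():
    """Small ideal helical bundle (single frame) plus its TM selection."""
    return gen_bundle(MicelleSimSpec(n_helices=4, helix_length=24, seed=0))


@pytest.fixture(scope="session")
def micelle():
    """Small proteomicelle trajectory with a mobile detergent shell."""
    spec = MicelleSimSpec(
        n_helices=4, helix_length=12, n_detergent=16, n_frames=8,
        mobility_sd=0.02, seed=5,
    )
    return gen_proteomicelle(spec)


def make_ensemble(coords, roles=None, elements=None, charges=None,
                  lj_eps=None, lj_sig=None, residue_ids=None,
                  residue_names=None, atom_names=None, times=None):
    """Hand-build a tiny ensemble for scripted-geometry tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(1, n + 1),
            "atom_name": atom_names if atom_names is not None else ["X"] * n,
            "element": elements if elements is not None else ["C"] * n,
            "residue_name": (residue_names if residue_names is not None
                             else ["UNK"] * n),
            "residue_id": (residue_ids if residue_ids is not None
                           else np.arange(1, n + 1)),
            "chain": "A",
            "role": roles if roles is not None else ["protein"] * n,
            "charge": charges if charges is not None else np.nan,
            "lj_epsilon": lj_eps if lj_eps is not None else np.nan,
            "lj_sigma": lj_sig if lj_sig is not None else np.nan,
        }
    )
    return AnnotatedEnsemble(atoms, coords, times=times)
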