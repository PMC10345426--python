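import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phnmr.synthetic import make_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(424242)


@pytest.fixture
def small_ensemble():
    """20-model jittered backbone ensemble with its ground-truth template."""
    return make_ensemble(n_residues=20, n_models=20, sigma=0.5, seed=7)


@pytest.fixture
def ensemble_pdb(tmp_path, small_ensemble):
    from phnmr.structure_io import write_ensemble

    ens, _tmpl = small_ensemble
    path = tmp_path / "ensemble.pdb"
    write_ensemble(ens, path)
    return path
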