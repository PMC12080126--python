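import warnings

import numpy as np
import pytest

from ensdock.fixtures import FixtureSpec, gen_prediction_bundle, gen_toy_ensemble

try:
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
except ImportError:
    pass


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return FixtureSpec(n_residues=30, n_frames=10, seed=11)


@pytest.fixture(scope="session")
def toy_ensemble(toy_spec):
    return gen_toy_ensemble(toy_spec)


@pytest.fixture(scope="session")
def toy_bundle(toy_spec, toy_ensemble):
    ens, _ = toy_ensemble
    return gen_prediction_bundle(toy_spec, ens.frames[0])


@pytest.fixture(autouse=True)
def _quiet_oversampling_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="target active fraction unreachable"
        )
        yield
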