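import logging

import numpy as np
import pytest

import loopscan as ls
from loopscan.synthetic import (
    SyntheticEnsembleSpec,
    build_synthetic_body,
    gaussian_ensemble,
    sample_loop_ensemble,
)

logging.getLogger("loopscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def loop_def():
    return ls.fviia_loop_definition()


@pytest.fixture(scope="session")
def numbering():
    return ls.fviia_numbering_map()


@pytest.fixture(scope="session")
def library(loop_def):
    return ls.enumerate_deletions(loop_def)


@pytest.fixture(scope="session")
def body():
    return build_synthetic_body(seed=0)


@pytest.fixture(scope="session")
def wt_ensemble(loop_def, body):
    """A moderate wild-type ensemble shared across geometry tests."""
    spec = SyntheticEnsembleSpec(n_poses=60, seed=11)
    ensemble, truth = sample_loop_ensemble(spec, loop_def, body=body)
    return ensemble, truth


@pytest.fixture()
def small_gaussian_ensemble():
    return gaussian_ensemble(n_poses=20, sigma=0.4, seed=5)
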