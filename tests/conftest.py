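import warnings

import numpy as np
import pytest

from tensoromics import generate, make_fixture_files

# MLP folds on tiny cohorts routinely hit the iteration cap; that is
# expected at test scale and not what any assertion is about.
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: N=300, M=80, K=3, R*=8, 4 labels."""
    tensor, labels, truth = generate(seed=11)
    return tensor, labels, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk file set for the default cohort (seed 3)."""
    out = tmp_path_factory.mktemp("fixture")
    tensor, labels, truth = generate(seed=3)
    make_fixture_files(truth, out)
    return out, tensor, labels, truth


@pytest.fixture(scope="session")
def ge_me_fixture_dir(tmp_path_factory):
    """Cohort whose components route alternately through GE and ME."""
    out = tmp_path_factory.mktemp("ge_me")
    tensor, labels, truth = generate(seed=5, omics_routing="ge_me")
    make_fixture_files(truth, out)
    return out, tensor, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
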