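import numpy as np
import pytest

from quantqtl.synthio import make_fixture_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory):
    """A small study bundle for pipeline/CLI tests (fast to scan)."""
    outdir = tmp_path_factory.mktemp("mini_bundle")
    paths = make_fixture_bundle(
        outdir, seed=11, n=200, n_genes=16, n_variants=600, q=5,
        n_location=4, n_scale=2, n_interaction=2,
    )
    return paths


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """The full-size miniature study used by the end-to-end checks."""
    outdir = tmp_path_factory.mktemp("study_bundle")
    return make_fixture_bundle(outdir, seed=7)
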