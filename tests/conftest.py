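import numpy as np
import pytest

import proxitome as px

SIX_SLOTS = (
    ("nt_kdm5", "control", "exp1"),
    ("ct_kdm5", "control", "exp1"),
    ("nt_kdm5", "control", "exp2"),
    ("ct_kdm5", "control", "exp2"),
    ("nt_kdm5", "dcas9", "exp2"),
    ("ct_kdm5", "dcas9", "exp2"),
)


@pytest.fixture(scope="session")
def six_specs():
    return [px.ComparisonSpec(b, r, e) for b, r, e in SIX_SLOTS]


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: fast enough for per-test use."""
    return px.SyntheticStudyConfig(
        n_proteins=300, n_true_shared=20, n_true_nt_only=6,
        n_true_ct_only=6, n_background_biased=30, seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    matrix, truth = px.generate_abundance_study(small_config)
    return small_config, matrix, truth


@pytest.fixture(scope="session")
def toy_sizes():
    return px.ChromSizes({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
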