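import pytest
from hypothesis import settings

from chromloop.insulation import expression_score
from chromloop.simulate import SimulationConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic cohort (seed 42) shared across tests."""
    return generate_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The default bundle written to disk, for I/O and CLI tests."""
    out = tmp_path_factory.mktemp("bundle")
    generate_dataset(SimulationConfig(), out_dir=out)
    return out


@pytest.fixture(scope="session")
def wt_expression_scores(default_bundle):
    """Length-normalized log10 WT expression per gene of the default bundle."""
    return {
        g.name: expression_score(
            default_bundle.expression[g.name].wt_count, g.length
        )
        for g in default_bundle.genes
    }
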