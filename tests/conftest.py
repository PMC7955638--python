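import pytest
from hypothesis import HealthCheck, settings

import polyresolve as pr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def example_corpus() -> pr.Corpus:
    """Packaged worked-example corpus: polystyrene, the PVA pair, DGEBA, nylon."""
    return pr.load_example_corpus()


@pytest.fixture(scope="session")
def pva_query() -> pr.SearchPackage:
    """The shared-abbreviation query: deparenthesized name plus 'PVA'."""
    return pr.SearchPackage(
        polfil="pol",
        chemical_name="polyvinyl alcohol",
        abbreviation="PVA",
        label="Poly(vinyl alcohol)",
    )


@pytest.fixture(scope="session")
def synth_corpus() -> pr.Corpus:
    """Mid-size synthetic corpus with two shared-abbreviation pairs."""
    return pr.generate_corpus_object(20, 2, seed=101)
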