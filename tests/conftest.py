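import pytest
from hypothesis import settings

from pdkg import corpus as corpus_mod
from pdkg import kg as kg_mod
from pdkg import synthetic

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    """The default five-study synthetic scenario with planted overlap."""
    return synthetic.pd_study_scenario(seed=0)


@pytest.fixture(scope="session")
def study_corpus(scenario):
    return corpus_mod.aggregate_corpus(
        scenario.deg_tables,
        core_protein_lists=scenario.core_proteins,
        dataset_context=scenario.dataset_context,
    )


@pytest.fixture(scope="session")
def monogenic_corpus(scenario):
    mono = {d: scenario.deg_tables[d] for d in synthetic.MONOGENIC_DATASETS}
    return corpus_mod.aggregate_corpus(
        mono,
        core_protein_lists={d: scenario.core_proteins[d] for d in mono},
        dataset_context={d: scenario.dataset_context[d] for d in mono},
    )


@pytest.fixture(scope="session")
def study_slices(scenario):
    return synthetic.generate_resource_slices(
        synthetic.pd_resource_spec(seed=0, universe_size=scenario.spec.universe_size)
    )


@pytest.fixture(scope="session")
def study_kg(study_corpus, study_slices):
    return kg_mod.build_graph(study_corpus, study_slices)
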