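import pytest

from seqcost import (
    FIXTURE_NAMES,
    MicroCostingModel,
    SyntheticParams,
    generate_cohort,
    load_fixture,
)


@pytest.fixture(scope="session")
def projects():
    """The six packaged example projects, keyed by name."""
    return {name: load_fixture(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def project_list(projects):
    return [projects[name] for name in FIXTURE_NAMES]


@pytest.fixture(scope="session")
def results(projects):
    """Fitted results for the six packaged projects."""
    return {name: MicroCostingModel(p).fit() for name, p in projects.items()}


@pytest.fixture(scope="session")
def cohort():
    """A reusable synthetic cohort with pairing, rework and all tiers."""
    params = SyntheticParams(n_projects=200, rework_rate=0.1, seed=20260923)
    return generate_cohort(params)
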