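import pytest

from stampc import reference, simulate


@pytest.fixture(scope="session")
def default_config():
    return simulate.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def registry(default_config):
    return simulate.generate_registry(default_config)


@pytest.fixture(scope="session")
def reports(registry, default_config):
    return simulate.generate_report_abstractions(registry, default_config)


@pytest.fixture(scope="session")
def survey():
    return simulate.generate_survey(
        reference.SURVEY_N_RATERS, dict(reference.SURVEY_MEAN_SD), seed=7
    )


@pytest.fixture(scope="session")
def sources(survey):
    return simulate.generate_source_scores(
        survey, reference.EXPERT_AUDIT_RANKS, reference.LITERATURE_FREQ
    )
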