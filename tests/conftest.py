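import pytest

import aquarisk as aq
from aquarisk import study


@pytest.fixture(scope="session")
def scenario():
    """Packaged residential scenario: (groups, context, registry)."""
    return aq.default_scenario()


@pytest.fixture(scope="session")
def study_records():
    return study.study_records()


@pytest.fixture(scope="session")
def study_summaries(study_records):
    return aq.summarize(study_records, study.SUPPLY_SITES, classes=study.CLASS_BY_ANALYTE)


@pytest.fixture(scope="session")
def study_assessment(study_records, scenario):
    """Full pipeline on the bundled study under the published configuration
    (uniform PCB-mixture slope factor, one-hit model, lifetime averaging)."""
    groups, ctx, registry = scenario
    return aq.run_assessment(
        study_records, study.SUPPLY_SITES, groups, ctx, registry, sf_config="as_published"
    )
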