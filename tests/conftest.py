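"""Shared fixtures: a small demo population run once per session."""

import pytest

from comorbarm import cohort, synthgen


@pytest.fixture(scope="session")
def demo_config():
    return synthgen.default_config(n_patients=2000, seed=1)


@pytest.fixture(scope="session")
def demo_population(demo_config):
    return synthgen.generate_population(demo_config)


@pytest.fixture(scope="session")
def demo_records(demo_population):
    return demo_population[0]


@pytest.fixture(scope="session")
def demo_truth(demo_population):
    return demo_population[1]


@pytest.fixture(scope="session")
def demo_cohort(demo_records):
    histories = cohort.build_histories(demo_records)
    kept, funnel = cohort.build_cohort(histories)
    return kept, funnel


@pytest.fixture(scope="session")
def demo_db(demo_cohort, demo_config):
    kept, _ = demo_cohort
    return cohort.build_transactions(
        kept, window=(demo_config.start_year, demo_config.end_year)
    )
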