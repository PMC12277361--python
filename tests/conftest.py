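import pytest

from stressnet.synthetic import StudyConfig, demo_experiments, generate_study


@pytest.fixture(scope="session")
def demo_study():
    """Two-experiment (10-condition) synthetic study, three species."""
    return generate_study(StudyConfig(experiments=demo_experiments()), seed=11)


@pytest.fixture(scope="session")
def full_study():
    """Full 31-condition synthetic study at the default scale."""
    return generate_study(seed=5)


@pytest.fixture(scope="session")
def demo_degs(demo_study):
    """DEG tables per species/condition for the demo study."""
    from stressnet.diffexp import call_all_degs

    return {sp: call_all_degs(demo_study.counts[sp]) for sp in demo_study.config.species}


@pytest.fixture(scope="session")
def demo_categories(demo_study):
    cats = {}
    for sp in demo_study.config.species:
        for row in demo_study.counts[sp].design.itertuples(index=False):
            cats[(row.experiment, str(row.level))] = row.category
    return cats
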