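import pytest

from seedatlas import SimulationConfig, simulate_cluster
from seedatlas.datasets import human_study, mouse_study
from seedatlas.nomenclature import Hairpin


@pytest.fixture(scope="session")
def mouse():
    return mouse_study()


@pytest.fixture(scope="session")
def human():
    return human_study()


@pytest.fixture(scope="session")
def mouse_calls(mouse):
    from seedatlas import assign_activity
    return assign_activity(mouse.reporters, mouse.outcomes, mouse.hairpins,
                           mouse.candidates)


@pytest.fixture(scope="session")
def human_calls(human):
    from seedatlas import assign_activity
    return assign_activity(human.reporters, human.outcomes, human.hairpins,
                           human.candidates)


@pytest.fixture(scope="session")
def sim_cluster():
    cfg = SimulationConfig(rng_seed=11)
    hairpins, truth = simulate_cluster(cfg)
    return cfg, hairpins, truth


@pytest.fixture
def toy_hairpin():
    # planted exact blocks: 5p block at 2, 3p block at 41
    seq = "GG" + "ACUCAAA" + "A" * 14 + "GCGC" + "A" * 14 + "AAAGUGC" + "CGCUU"
    return Hairpin(id="toy", sequence=seq, anchor_5p0=2, anchor_3p0=41)
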