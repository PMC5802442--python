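import pytest
from hypothesis import settings

import lungsim as ls

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return ls.default_config()


@pytest.fixture(scope="session")
def sim_cfg():
    """Moderate-size default-parameter configuration shared by simulation tests."""
    return ls.default_config().replace(
        population={"n_persons": 30_000, "master_seed": 20250901})


@pytest.fixture(scope="session")
def baseline_result(sim_cfg):
    """One full default-parameter replication (screening vs no screening)."""
    return ls.run_replication(sim_cfg, 20250901)


@pytest.fixture(scope="session")
def small_pairs():
    """Per-person outcome pairs for a small default-parameter population."""
    cfg = ls.default_config().replace(
        population={"n_persons": 6_000, "master_seed": 555})
    persons = ls.build_population(cfg.population, cfg.smoking)
    pairs = []
    for p in persons:
        course = ls.compute_course(p, cfg)
        ns, sc = ls.simulate_person_pair(p, cfg, course=course)
        pairs.append((p, course, ns, sc))
    return cfg, pairs
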