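import numpy as np
import pytest

from clonalmap.markers import JointCounts, MarkerCategory, PopulationType, Scenario
from clonalmap.pipeline import run_pipeline
from clonalmap.simulate import demo20_config, simulate_population

# representative category pair per scenario (canonical orientation)
SCENARIO_CATS = {
    1: (MarkerCategory.I, MarkerCategory.I),
    2: (MarkerCategory.I, MarkerCategory.II),
    3: (MarkerCategory.I, MarkerCategory.III),
    4: (MarkerCategory.I, MarkerCategory.IV),
    5: (MarkerCategory.II, MarkerCategory.II),
    6: (MarkerCategory.II, MarkerCategory.IV),
    7: (MarkerCategory.III, MarkerCategory.III),
    8: (MarkerCategory.III, MarkerCategory.IV),
    9: (MarkerCategory.IV, MarkerCategory.IV),
    10: (MarkerCategory.I, MarkerCategory.V),
    11: (MarkerCategory.II, MarkerCategory.V),
    12: (MarkerCategory.III, MarkerCategory.V),
    13: (MarkerCategory.IV, MarkerCategory.V),
    14: (MarkerCategory.V, MarkerCategory.V),
}


def make_joint_counts(scenario_id, counts):
    """JointCounts wrapper for tests feeding counts straight to an estimator."""
    c1, c2 = SCENARIO_CATS[scenario_id]
    scen = Scenario(scenario_id, c1, c2, swapped=False, est_rf=True, est_rm=True)
    return JointCounts(scenario=scen, counts=tuple(counts))


@pytest.fixture(scope="session")
def demo_population():
    """One seeded 20-marker clonal F1 population with its generating truth."""
    cfg = demo20_config()
    gm, truth = simulate_population(cfg, np.random.default_rng(20260101))
    return gm, truth


@pytest.fixture(scope="session")
def demo_result(demo_population):
    gm, _ = demo_population
    return run_pipeline(gm)
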