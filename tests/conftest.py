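import numpy as np
import pytest

from superchild.cohort import generate_cohort
from superchild.kinetics import ModelSpec
from superchild.population import FitConfig, PopulationTracerModel
from superchild.protocols import (EXTENSIVE36, REDUCED11, build_protocol2,
                                  simulate_cohort_curves)


@pytest.fixture(scope="session")
def cohort1():
    """The 50-child high-intake cohort at seed 1."""
    return generate_cohort("high_intake_50", seed=1)


@pytest.fixture(scope="session")
def curves11(cohort1):
    return simulate_cohort_curves(cohort1, REDUCED11)


@pytest.fixture(scope="session")
def curves36(cohort1):
    return simulate_cohort_curves(cohort1, EXTENSIVE36)


@pytest.fixture(scope="session")
def p2_results(cohort1, curves11):
    """Protocol-2 fit of the seed-1 cohort (validation mode)."""
    comp = build_protocol2(cohort1, curves11)
    model = PopulationTracerModel(comp, cohort1.gm_m5,
                                  FitConfig("simplified", "auto", 0.01))
    return model.fit(seed=1, known_tbs=cohort1.gm_tbs)


@pytest.fixture(scope="session")
def gm_spec_simplified():
    """Simplified one-pool model at the known geometric-mean coefficients."""
    return ModelSpec(
        "simplified", 1,
        {(5, 4): 5.0, (6, 5): 30.1, (5, 6): 0.0502, (10, 6): 0.00597},
        dt3=0.3, absorption=0.8,
    )


@pytest.fixture(scope="session")
def gm_spec_full():
    """Full two-pool model at the known geometric-mean coefficients."""
    return ModelSpec(
        "full", 2,
        {(2, 1): 50.0, (3, 2): 50.0, (5, 4): 5.0, (6, 5): 30.1,
         (5, 6): 0.0502, (10, 6): 0.00597, (7, 5): 31.9, (5, 7): 1.67},
        dt3=0.18, absorption=0.8,
    )
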