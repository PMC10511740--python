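import numpy as np
import pytest

from mmnathist.cohort import AgeGrid
from mmnathist.likelihood import ModelContext
from mmnathist.synthetic import (SyntheticDesign, generate_truth_curves,
                                 sample_observations)


@pytest.fixture(scope="session")
def design():
    return SyntheticDesign(seed=1)


@pytest.fixture(scope="session")
def mortality(design):
    return design.mortality_schedule()


@pytest.fixture(scope="session")
def population(design):
    return design.population_table()


@pytest.fixture(scope="session")
def truth_curves(design):
    return generate_truth_curves(design)


@pytest.fixture(scope="session")
def context(design, mortality, population, truth_curves):
    """A fit-ready context around one sampled synthetic observation set."""
    prev, inc = sample_observations(truth_curves, design)
    return ModelContext(mortality, population, AgeGrid(), prev, inc)


def plausible_parameters(rng: np.random.Generator):
    """Random parameter vectors in the epidemiologically plausible
    region (rates well below 1/yr at all ages), for property tests."""
    from mmnathist.params import ParameterVector

    ages = np.arange(100.0)
    b1a = rng.uniform(0.0, 0.08)
    b2a = rng.uniform(0.0, 0.2)
    b2a2 = rng.uniform(-0.002, 0.0)
    peak_mm = float(np.max(b2a * ages + b2a2 * ages ** 2))
    return ParameterVector(
        gamma_mgus=rng.uniform(-12.0, -6.0) - 99.0 * b1a * rng.uniform(0.3, 1.0),
        beta_mgus_a=b1a,
        beta_mgus_s=rng.uniform(-1.0, 1.0),
        beta_mgus_r=rng.uniform(-1.0, 1.0),
        gamma_mm=rng.uniform(-12.0, -5.0) - peak_mm,
        beta_mm_a=b2a,
        beta_mm_a2=b2a2,
        beta_mm_s=rng.uniform(-1.0, 1.0),
        beta_mm_r=rng.uniform(-1.0, 1.0),
        tau2=rng.uniform(0.001, 1.0),
    )
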