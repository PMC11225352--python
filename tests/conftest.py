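import numpy as np
import pytest

from silkstudy.cohort import (CohortConfig, InfusionSpec, generate_cohort,
                              simulate_leucine_enrichment)
from silkstudy.compartment import KineticParameters, simulate
from silkstudy.data_model import (ConcentrationSeries, SampleSchedule,
                                  SilkSeries)


@pytest.fixture(scope="session")
def schedule():
    return SampleSchedule.default()


@pytest.fixture(scope="session")
def enrichment():
    return simulate_leucine_enrichment(InfusionSpec())


@pytest.fixture(scope="session")
def default_params():
    return KineticParameters.default()


@pytest.fixture(scope="session")
def noise_free_output(default_params, enrichment, schedule):
    return simulate(default_params, enrichment, schedule)


@pytest.fixture(scope="session")
def study():
    """One seeded default synthetic study shared across tests."""
    return generate_cohort(CohortConfig(seed=7))


def make_series(subject_id="S1", isoform="Ab40", times=None, values=None,
                missing=None):
    times = np.arange(0, 37, 2.0) if times is None else np.asarray(times, float)
    values = np.zeros_like(times) if values is None else np.asarray(values, float)
    missing = np.zeros(len(times), bool) if missing is None \
        else np.asarray(missing, bool)
    return SilkSeries(subject_id, isoform, times, values, missing)


def make_conc(subject_id="S1", analyte="Ab40", matrix="CSF", times=None,
              values=None, missing=None, clock=None):
    times = np.arange(0, 37, 2.0) if times is None else np.asarray(times, float)
    values = np.ones_like(times) if values is None else np.asarray(values, float)
    missing = np.zeros(len(times), bool) if missing is None \
        else np.asarray(missing, bool)
    return ConcentrationSeries(subject_id, analyte, matrix, times, values,
                               missing, clock_minutes=clock)
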