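import numpy as np
import pytest

from qreslife import StudyData, SubjectRecord, fractional_polynomial_basis


@pytest.fixture(scope="session")
def fp_basis():
    return fractional_polynomial_basis()


@pytest.fixture
def toy_data():
    """Three subjects, two scheduled visits, p = q = 1.

    Subject a: uncensored failure at 2.0, attends both visits.
    Subject b: censored at 1.5, attends the first visit only.
    Subject c: uncensored failure at 0.9, attends the first visit.
    """
    schedule = np.array([0.25, 0.5])
    subjects = [
        SubjectRecord("a", 2.0, 1, [1.0], [1, 1], [[0.3], [-0.2]]),
        SubjectRecord("b", 1.5, 0, [0.0], [1, 0], [[0.8], [np.nan]]),
        SubjectRecord("c", 0.9, 1, [1.0], [1, 0], [[-0.5], [np.nan]]),
    ]
    return StudyData(subjects, schedule)


@pytest.fixture(scope="session")
def setup2_fit():
    """A converged induced-smoothed fit on a moderate Setup II cohort."""
    from qreslife import induced_smoothing_estimate, simulate_setup2

    sim = simulate_setup2(400, tau=0.5, seed=20240)
    fit = induced_smoothing_estimate(sim.data, 0.5, fractional_polynomial_basis())
    assert fit.converged
    return sim, fit
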