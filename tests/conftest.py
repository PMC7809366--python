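import numpy as np
import pytest

from holomass import spectral, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """A 300-cell default cohort (seed 1), shared across tests."""
    cfg = synthetic.CohortConfig(n_cells=300, seed=1)
    traces, truth = synthetic.generate_cohort(cfg)
    return traces, truth


@pytest.fixture(scope="session")
def default_cohort_report(default_cohort):
    traces, _ = default_cohort
    cohort = spectral.average_spectra(spectral.compute_cell_spectra(traces))
    report = spectral.find_fundamental(cohort)
    return cohort, report


@pytest.fixture(scope="session")
def default_scene():
    """The default imaging scene (seed 0) with rendered phase frames."""
    truth = synthetic.generate_scene(seed=0)
    stack = synthetic.render_phase_frames(truth)
    return truth, stack
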