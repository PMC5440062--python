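import numpy as np
import pytest

from primadapt.analysis import AnalysisWindow
from primadapt.cohort import CohortSpec, NoiseModel, generate_cohort
from primadapt.kinematics import min_jerk_reach


@pytest.fixture(scope="session")
def criterion_reach():
    """The canonical 10 cm reach at the 0.30 m/s criterion peak speed."""
    return min_jerk_reach(0.10, 0.30)


@pytest.fixture(scope="session")
def coarse_window():
    """Analysis window on a 4 ms grid, for fast pipeline tests."""
    return AnalysisWindow(dt=0.004)


@pytest.fixture(scope="session")
def silent_pff_cohort():
    """Two-subject zero-noise pFF cohort on a coarse grid (exact round trips)."""
    spec = CohortSpec(ff_type="pFF", n_subjects=2, noise=NoiseModel(0.0, 0.0, 0.0), dt=0.004)
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_vff_cohort():
    """Six-subject vFF cohort at the default noise level, coarse grid."""
    spec = CohortSpec(ff_type="vFF", n_subjects=6, dt=0.004)
    return generate_cohort(spec, seed=5)
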