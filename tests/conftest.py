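import numpy as np
import pytest

from dynstates import RoiCohort, make_ground_truth, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort(rng):
    """3 subjects x (4 ROIs x 30 volumes) of plain noise."""
    series = [rng.normal(size=(4, 30)) for _ in range(3)]
    return RoiCohort(
        subjects=["s0", "s1", "s2"],
        series=series,
        roi_labels=["A", "B", "C", "D"],
        tr_seconds=3.0,
        condition="test",
    )


@pytest.fixture(scope="session")
def planted_study():
    """A small two-state-structure study shared by several test modules."""
    gt = make_ground_truth(
        K_true=3, D=10, sink_mass=0.4, block_sizes=[5, 5], separation=6.0, seed=7
    )
    syn = simulate_cohort(gt, N=5, T=120, tr=3.0, obs_noise=0.2, seed=8)
    return gt, syn
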