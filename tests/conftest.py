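import numpy as np
import pytest

from paleoterm.io import CalibrationCurve, CountMatrix
from paleoterm.synthetic import gen_fossil_sequence, gen_training_set


@pytest.fixture
def identity_curve():
    """Curve with 14C age == cal age and zero curve error."""
    grid = np.arange(0.0, 10001.0, 5.0)
    return CalibrationCurve(grid, grid.copy(), np.zeros_like(grid))


@pytest.fixture
def toy_counts():
    return CountMatrix(
        sample_ids=["s1", "s2"],
        taxa=["Pinus", "Quercus", "Artemisia"],
        counts=np.array([[10.0, 5.0, 5.0], [0.0, 8.0, 12.0]]),
        depths=np.array([10.0, 20.0]),
    )


@pytest.fixture(scope="session")
def gaussian_benchmark():
    """The synthetic Gaussian-response benchmark: 40 taxa, optima over
    5-25 degC, tolerance 2 degC, n=150 modern samples of 300 grains, plus a
    30-sample downcore sequence over a known linear trajectory."""
    training, truth = gen_training_set(
        n_taxa=40, n_samples=150, optima_range=(5.0, 25.0), tolerance=2.0,
        grains_per_sample=300, seed=7,
    )
    trajectory = np.linspace(8.0, 22.0, 30)
    fossil, ftruth = gen_fossil_sequence(trajectory, truth, grains=300, seed=8)
    return {
        "training": training,
        "truth": truth,
        "fossil": fossil,
        "trajectory": trajectory,
    }
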