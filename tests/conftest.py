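import numpy as np
import pytest

from trajmix import DesignSpec, LongitudinalDataset, build_design


@pytest.fixture
def toy_dataset():
    """Three subjects, ragged lengths, strictly positive responses."""
    return LongitudinalDataset(
        subject_ids=["a", "b", "c"],
        times=[np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0]), np.array([1.0, 2.0, 3.0])],
        responses=[np.array([1.0, 2.0, 4.0]), np.array([0.5, 3.0]), np.array([2.0, 2.0, 5.0])],
    )


@pytest.fixture
def balanced_dataset():
    """Four subjects on a common 3-point grid (equal p_i)."""
    rng = np.random.default_rng(42)
    t = np.array([0.0, 1.0, 2.0])
    return LongitudinalDataset(
        subject_ids=list(range(4)),
        times=[t] * 4,
        responses=[np.exp(rng.normal(1.0, 0.3, 3)) for _ in range(4)],
    )


@pytest.fixture
def line_design():
    return DesignSpec.polynomial(1)
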