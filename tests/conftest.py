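import numpy as np
import pytest

from invaspect.io import RawBoundary


@pytest.fixture
def unit_square() -> RawBoundary:
    return RawBoundary(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
                       tumor_id="T1", organoid_id="O1")


@pytest.fixture
def right_triangle() -> RawBoundary:
    return RawBoundary(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))


@pytest.fixture
def dense_circle() -> RawBoundary:
    theta = 2.0 * np.pi * np.arange(1000) / 1000
    return RawBoundary(np.column_stack([np.cos(theta), np.sin(theta)]))


@pytest.fixture
def star_shape() -> RawBoundary:
    """r(θ) = 1 + 0.1·cos(6θ), densely traced."""
    theta = 2.0 * np.pi * np.arange(4000) / 4000
    r = 1.0 + 0.1 * np.cos(6 * theta)
    return RawBoundary(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
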