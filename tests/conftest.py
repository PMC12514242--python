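import numpy as np
import pytest

from npcloud import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table_2d():
    return LocalizationTable(
        x=np.array([100.0, 150.0, 110.0]),
        y=np.array([200.0, 250.0, 210.0]),
        frame=np.array([1, 2, 1]),
    )


@pytest.fixture
def table_3d():
    return LocalizationTable(
        x=np.array([100.0, 150.0, 110.0]),
        y=np.array([200.0, 250.0, 210.0]),
        z=np.array([-50.0, 20.0, 5.0]),
        frame=np.array([1, 2, 1]),
    )


def grid_table(spacing=200.0, n_side=10, frame=1):
    """Regular grid of localizations, spacing in nm, all in one frame."""
    xs, ys = np.meshgrid(
        np.arange(n_side) * spacing, np.arange(n_side) * spacing
    )
    n = xs.size
    return LocalizationTable(
        x=xs.ravel(), y=ys.ravel(), frame=np.full(n, frame, dtype=np.int64)
    )
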