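import numpy as np
import pytest

from connscreen.fc import FCMatrix


def z_matrix(edge_values, n_rois=None, tag=""):
    """Build a z-domain FCMatrix from {(i, j): z} off-diagonal values."""
    if n_rois is None:
        n_rois = 1 + max(max(i, j) for i, j in edge_values)
    values = np.zeros((n_rois, n_rois))
    for (i, j), z in edge_values.items():
        values[i, j] = values[j, i] = z
    np.fill_diagonal(values, np.nan)
    names = tuple(f"ROI{i + 1:02d}" for i in range(n_rois))
    m = FCMatrix(np.zeros((n_rois, n_rois)), "z", names, tag=tag)
    m.values = values
    return m


def z_group(edge_samples, n_rois=2):
    """One z-domain FCMatrix per animal from per-edge value lists.

    ``edge_samples`` maps (i, j) -> sequence of per-animal z values.
    """
    n_animals = len(next(iter(edge_samples.values())))
    return [z_matrix({e: vals[a] for e, vals in edge_samples.items()}, n_rois)
            for a in range(n_animals)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
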