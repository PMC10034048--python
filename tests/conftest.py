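"""Shared fixtures: synthetic subjects at desk scale, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from trihinge.labeling import LabelingConfig, expand_regions
from trihinge.synthetic import SynthConfig, generate_subject


@pytest.fixture(scope="session")
def desk_subject():
    """A 120x120 mm sheet with ~20 planted triple junctions."""
    return generate_subject(SynthConfig(seed=1, grid_shape=(120, 120), n_cells=12))


@pytest.fixture(scope="session")
def desk_labels(desk_subject):
    return expand_regions(desk_subject.surface, desk_subject.annotation, LabelingConfig())


@pytest.fixture(scope="session")
def small_subject():
    """A 48x48 mm sheet, cheap enough for brute-force oracles."""
    return generate_subject(SynthConfig(seed=3, grid_shape=(48, 48), n_cells=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def flat_sheet(rows: int, cols: int, spacing: float = 1.0):
    """A flat rectangular grid surface (z = 0) for hand-constructed cases."""
    from trihinge.io import CorticalSurface
    from trihinge.synthetic import _grid_faces

    xs = np.arange(cols) * spacing
    ys = np.arange(rows) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(rows * cols)])
    return CorticalSurface(vertices=vertices, faces=_grid_faces(rows, cols))
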