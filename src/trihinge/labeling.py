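"""Expansion of hinge vertices into binary 3-hinge region labels.

A surface vertex belongs to the 3-hinge region iff it lies within a spherical
(ambient Euclidean) neighborhood of radius ``R1`` of any 3-hinge vertex or
radius ``R2`` of any 2-hinge vertex; the defaults R1 = 6 mm and R2 = 2 mm
follow the empirical radii used for gyral hinge labeling. The expansion runs
over all surface vertices, and vertices matching both conditions are labeled
once (set union).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError
from .io import CorticalSurface, HingeAnnotation

__all__ = ["LabelingConfig", "expand_regions"]


@dataclass(frozen=True)
class LabelingConfig:
    """Expansion radii in mm around 3-hinge (R1) and 2-hinge (R2) vertices."""

    R1: float = 6.0
    R2: float = 2.0

    def validate(self) -> None:
        if self.R1 < 0 or self.R2 < 0:
            raise ConfigError("R1 and R2 must be >= 0")


def expand_regions(
    surface: CorticalSurface,
    annotation: HingeAnnotation,
    cfg: LabelingConfig = LabelingConfig(),
) -> np.ndarray:
    """Binary per-vertex labels: 1 inside the expanded 3-hinge region.

    ``label[v] = 1`` iff the Euclidean distance from v to some 3-hinge vertex
    is <= R1 or to some 2-hinge vertex is <= R2. An empty annotation yields
    all-zero labels with a warning.
    """
    cfg.validate()
    annotation.validate_against(surface)
    labels = np.zeros(surface.n_vertices, dtype=np.uint8)
    if annotation.two_hinge_idx.size == 0 and annotation.three_hinge_idx.size == 0:
        warnings.warn("hinge annotation is empty; labels are all zero", stacklevel=2)
        return labels
    tree = cKDTree(surface.vertices)
    for idx, radius in (
        (annotation.three_hinge_idx, cfg.R1),
        (annotation.two_hinge_idx, cfg.R2),
    ):
        if idx.size == 0:
            continue
        hits = tree.query_ball_point(surface.vertices[idx], r=radius)
        for h in hits:
            labels[h] = 1
        labels[idx] = 1  # radius 0 still labels the annotated vertex itself
    return labels
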