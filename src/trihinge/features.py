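"""Per-vertex KNN feature aggregation, normalization and blocking.

Each vertex's input to the segmentation network is the 16-vector
``[a, b1, ..., b15]``: its own morphometry value followed by the values of
its k = 15 nearest vertices (ambient Euclidean distance, ascending). The
per-subject feature matrix is min-max normalized to [0, 1], zero-padded to
the next multiple of 64*64 = 4096 rows, and tiled into (64, 64, k+1) blocks;
an index map makes the tiling invertible so block predictions can be mapped
back onto vertices exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DimensionError
from .io import CorticalSurface

__all__ = [
    "FeatureConfig",
    "FeatureBlocks",
    "KNNFeatureAggregator",
    "knn_vectors",
    "normalize_minmax",
    "pad_and_block",
    "unblock",
    "save_blocks",
    "load_blocks",
]

PAD = -1


@dataclass(frozen=True)
class FeatureConfig:
    """KNN size and block geometry; network channels are always k + 1."""

    k: int = 15
    block_rows: int = 64
    block_cols: int = 64
    feature_names: tuple[str, ...] = ("sulc",)

    @property
    def channels(self) -> int:
        return self.k + 1

    @property
    def block_size(self) -> int:
        return self.block_rows * self.block_cols

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.block_rows < 1 or self.block_cols < 1:
            raise ConfigError("block dimensions must be >= 1")
        if not self.feature_names:
            raise ConfigError("feature_names must not be empty")


@dataclass
class FeatureBlocks:
    """Blocked feature tensors with a shared, invertible vertex-slot map.

    ``tensors`` maps feature name -> (n_blocks, rows, cols, channels) array;
    ``vertex_index_map`` holds the original vertex id per slot (PAD = -1);
    ``pad_mask`` is True on padding slots.
    """

    tensors: dict[str, np.ndarray]
    vertex_index_map: np.ndarray
    pad_mask: np.ndarray
    n_vertices_original: int
    config: FeatureConfig = dc_field(default_factory=FeatureConfig)

    @property
    def n_blocks(self) -> int:
        return int(self.vertex_index_map.shape[0])

    @property
    def feature_names(self) -> list[str]:
        return list(self.tensors)

    def stacked(self, order: list[str] | None = None) -> list[np.ndarray]:
        return [self.tensors[name] for name in (order or self.feature_names)]


# ---------------------------------------------------------------------------
# KNN aggregation
# ---------------------------------------------------------------------------

class KNNFeatureAggregator(BaseEstimator, TransformerMixin):
    """Aggregate per-vertex scalars into [self, k nearest neighbors] vectors.

    Fit on vertex coordinates; transform any per-vertex scalar map of the same
    surface into an (n, k+1) matrix. Neighbors are sorted ascending by
    Euclidean distance with ties broken by lower vertex index, so the output
    is deterministic; the vertex itself is excluded from its neighbor list.
    """

    def __init__(self, k: int = 15):
        self.k = k

    def fit(self, X, y=None):
        coords = np.asarray(X, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DimensionError(f"coordinates must be (n, 3), got {coords.shape}")
        n = coords.shape[0]
        if self.k >= n:
            raise ConfigError(f"k={self.k} must be < n_vertices={n}")
        self.n_vertices_ = n
        self.neighbor_indices_ = self._neighbors(coords)
        return self

    def _neighbors(self, coords: np.ndarray) -> np.ndarray:
        n, k = coords.shape[0], self.k
        tree = cKDTree(coords)
        m = min(n, k + 33)
        while True:
            _, idx = tree.query(coords, k=m)
            idx = np.atleast_2d(idx)
            # exact squared distances recomputed from coordinates so that
            # equal lattice distances compare exactly equal
            diff = coords[idx] - coords[:, None, :]
            d2 = np.einsum("nmk,nmk->nm", diff, diff)
            d2[idx == np.arange(n)[:, None]] = np.inf  # drop self by identity
            # sort by index first, then stable-sort by distance: ties at equal
            # distance resolve to the lower vertex index
            oi = np.argsort(idx, axis=1, kind="stable")
            idx_s = np.take_along_axis(idx, oi, axis=1)
            d2_s = np.take_along_axis(d2, oi, axis=1)
            od = np.argsort(d2_s, axis=1, kind="stable")
            idx_s = np.take_along_axis(idx_s, od, axis=1)
            d2_s = np.take_along_axis(d2_s, od, axis=1)
            if m >= n:
                break
            # the k-th kept distance must be strictly inside the fetched
            # radius, otherwise an equally-distant candidate may be missing
            if np.all(d2_s[:, k - 1] < d2_s[:, m - 1]):
                break
            m = min(n, 2 * m)
        return idx_s[:, :k].astype(np.int64)

    def transform(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64).ravel()
        if values.size != self.n_vertices_:
            raise DimensionError(
                f"map has {values.size} values, surface has {self.n_vertices_}"
            )
        return np.column_stack([values, values[self.neighbor_indices_]])


def knn_vectors(surface: CorticalSurface, values: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Functional wrapper over :class:`KNNFeatureAggregator`."""
    cfg.validate()
    agg = KNNFeatureAggregator(k=cfg.k).fit(surface.vertices)
    return agg.transform(values)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_minmax(matrix: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Scale a feature matrix to [0, 1] by its global min/max.

    The min and max are taken over all valid entries of the matrix (one
    feature, one subject-hemisphere); rows excluded by ``mask`` stay 0. A
    constant matrix maps to all zeros with a warning.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    out = np.zeros_like(matrix)
    valid = np.ones(matrix.shape[0], dtype=bool) if mask is None else np.asarray(mask, bool)
    if matrix.shape[0] != valid.size:
        raise DimensionError("mask length must equal the number of rows")
    if not valid.any():
        return out
    sub = matrix[valid]
    vmin, vmax = float(sub.min()), float(sub.max())
    if vmax <= vmin:
        warnings.warn("constant feature: min == max, normalized to all zeros", stacklevel=2)
        return out
    out[valid] = (sub - vmin) / (vmax - vmin)
    return out


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

def pad_and_block(matrices, cfg: FeatureConfig = FeatureConfig()) -> FeatureBlocks:
    """Zero-pad feature matrices and tile them into (rows, cols, channels) blocks.

    Row i of the padded matrix lands at block ``i // (rows*cols)``, row
    ``(i % (rows*cols)) // cols``, column ``i % cols``. Accepts one (n, c)
    matrix or a dict of equally-shaped matrices (multi-feature fusion input);
    all tensors share one vertex index map.
    """
    cfg.validate()
    if not isinstance(matrices, dict):
        matrices = {cfg.feature_names[0]: matrices}
    names = list(matrices)
    first = np.asarray(matrices[names[0]], dtype=np.float64)
    if first.ndim == 1:
        first = first[:, None]
    n = first.shape[0]
    if n < 1:
        raise DimensionError("feature matrix must have at least one row")
    bs = cfg.block_size
    n_blocks = -(-n // bs)  # ceil
    padded_len = n_blocks * bs

    flat_ids = np.full(padded_len, PAD, dtype=np.int64)
    flat_ids[:n] = np.arange(n)
    vertex_index_map = flat_ids.reshape(n_blocks, cfg.block_rows, cfg.block_cols)
    pad_mask = vertex_index_map == PAD

    tensors = {}
    for name in names:
        mat = np.asarray(matrices[name], dtype=np.float64)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.shape[0] != n:
            raise DimensionError("all feature matrices must have the same number of rows")
        c = mat.shape[1]
        buf = np.zeros((padded_len, c))
        buf[:n] = mat
        tensors[name] = buf.reshape(n_blocks, cfg.block_rows, cfg.block_cols, c)
    return FeatureBlocks(
        tensors=tensors,
        vertex_index_map=vertex_index_map,
        pad_mask=pad_mask,
        n_vertices_original=n,
        config=cfg,
    )


def unblock(blocks: FeatureBlocks, predictions: np.ndarray) -> np.ndarray:
    """Map blocked per-slot values back to per-vertex values, dropping padding."""
    predictions = np.asarray(predictions)
    expect = blocks.vertex_index_map.shape
    if predictions.shape[:3] != expect:
        raise DimensionError(
            f"predictions shape {predictions.shape[:3]} does not match block layout {expect}"
        )
    flat_ids = blocks.vertex_index_map.reshape(-1)
    flat = predictions.reshape(flat_ids.size, *predictions.shape[3:])
    keep = flat_ids != PAD
    out_shape = (blocks.n_vertices_original, *predictions.shape[3:])
    out = np.zeros(out_shape, dtype=predictions.dtype)
    out[flat_ids[keep]] = flat[keep]
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_blocks(blocks: FeatureBlocks, path) -> Path:
    """One binary tensor container per subject plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"tensor_{k}": v for k, v in blocks.tensors.items()}
    np.savez_compressed(
        path, vertex_index_map=blocks.vertex_index_map, **arrays,
    )
    sidecar = {
        "n_vertices_original": blocks.n_vertices_original,
        "n_blocks": blocks.n_blocks,
        "feature_names": blocks.feature_names,
        "config": {
            "k": blocks.config.k,
            "block_rows": blocks.config.block_rows,
            "block_cols": blocks.config.block_cols,
            "feature_names": list(blocks.config.feature_names),
        },
    }
    side = path.with_suffix(".json")
    side.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def load_blocks(path) -> FeatureBlocks:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        vim = data["vertex_index_map"]
        tensors = {
            k[len("tensor_"):]: data[k] for k in data.files if k.startswith("tensor_")
        }
    cfgd = side["config"]
    cfg = FeatureConfig(
        k=cfgd["k"], block_rows=cfgd["block_rows"], block_cols=cfgd["block_cols"],
        feature_names=tuple(cfgd["feature_names"]),
    )
    return FeatureBlocks(
        tensors=tensors,
        vertex_index_map=vim,
        pad_mask=vim == PAD,
        n_vertices_original=side["n_vertices_original"],
        config=cfg,
    )
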