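"""Surface, morphometry-map and annotation I/O.

Reads and writes the formats a FreeSurfer-based surface pipeline produces:
binary surface geometry (``lh.white`` style), per-vertex ``curv``/morph scalar
files, GIfTI surface and functional files, plain-text hinge vertex-index
lists, CSV centroid tables and JSON metric reports.

Vertex indices are 0-based everywhere; coordinates stay in the file's native
surface-RAS frame (all distances in the pipeline are intra-subject, so no
registration is performed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError

__all__ = [
    "CorticalSurface",
    "MorphMaps",
    "HingeAnnotation",
    "read_surface",
    "write_surface",
    "read_morph",
    "write_morph",
    "read_index_list",
    "write_index_list",
    "read_centroid_csv",
    "write_centroid_csv",
    "write_outputs",
]

MORPH_NAMES = ("sulc", "curv", "thick", "area", "vol")


@dataclass
class CorticalSurface:
    """A triangulated cortical sheet or hemisphere surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm (surface RAS or synthetic sheet frame).
    faces : (m, 3) int array
        Vertex-index triples, 0-based.
    hemisphere : {"lh", "rh"}
        Hemisphere tag; synthetic sheets default to "lh".
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "lh"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DimensionError(f"faces must be (m, 3), got {self.faces.shape}")
        n = self.n_vertices
        if n < 3:
            raise FormatError(f"surface needs at least 3 vertices, got {n}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            bad = int(np.flatnonzero((self.faces < 0).any(1) | (self.faces >= n).any(1))[0])
            raise FormatError(
                f"face {bad} references a vertex outside [0, {n}): {self.faces[bad].tolist()}"
            )
        if self.faces.size:
            degen = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degen.any():
                raise FormatError(f"degenerate face at row {int(np.flatnonzero(degen)[0])}")
        if self.hemisphere not in ("lh", "rh"):
            raise FormatError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges as a (n_edges, 2) sorted-index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)


@dataclass
class MorphMaps:
    """Named per-vertex scalar morphometry maps (sulc, curv, thick, area, vol)."""

    maps: dict[str, np.ndarray] = field(default_factory=dict)
    n_vertices: int | None = None

    def __post_init__(self) -> None:
        for name, arr in list(self.maps.items()):
            self.maps[name] = self._validate(name, arr)

    def _validate(self, name: str, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=np.float64).ravel()
        if not np.isfinite(arr).all():
            raise FormatError(f"morph map {name!r} contains non-finite values")
        if self.n_vertices is None:
            self.n_vertices = arr.size
        elif arr.size != self.n_vertices:
            raise DimensionError(
                f"morph map {name!r} has {arr.size} values, expected {self.n_vertices}"
            )
        return arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def __setitem__(self, name: str, arr: np.ndarray) -> None:
        self.maps[name] = self._validate(name, arr)

    def __contains__(self, name: str) -> bool:
        return name in self.maps

    def names(self) -> list[str]:
        return list(self.maps)


@dataclass
class HingeAnnotation:
    """2-hinge / 3-hinge vertex lists plus ground-truth 3-hinge centroids.

    2-hinges lie on gyral crest lines between junctions; 3-hinges are the
    triple-junction vertices where three crests meet. Centroid coordinates are
    the exact junction points (mm).
    """

    two_hinge_idx: np.ndarray
    three_hinge_idx: np.ndarray
    three_hinge_centroids: np.ndarray

    def __post_init__(self) -> None:
        self.two_hinge_idx = np.asarray(self.two_hinge_idx, dtype=np.int64).ravel()
        self.three_hinge_idx = np.asarray(self.three_hinge_idx, dtype=np.int64).ravel()
        self.three_hinge_centroids = np.asarray(
            self.three_hinge_centroids, dtype=np.float64
        ).reshape(-1, 3)
        overlap = np.intersect1d(self.two_hinge_idx, self.three_hinge_idx)
        if overlap.size:
            raise FormatError(
                f"2-hinge and 3-hinge index lists overlap at vertex {int(overlap[0])}"
            )

    def validate_against(self, surface: CorticalSurface) -> None:
        n = surface.n_vertices
        for name, idx in (("two_hinge", self.two_hinge_idx), ("three_hinge", self.three_hinge_idx)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise FormatError(f"{name} index list contains an index outside [0, {n})")


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def _infer_hemisphere(path: Path, hemisphere: str | None) -> str:
    if hemisphere is not None:
        return hemisphere
    name = path.name.lower()
    if name.startswith("rh") or ".rh." in name:
        return "rh"
    return "lh"


def read_surface(path, fmt: str = "freesurfer", hemisphere: str | None = None) -> CorticalSurface:
    """Read a triangular surface mesh.

    ``fmt`` is ``"freesurfer"`` (binary geometry) or ``"gifti"``. The
    hemisphere tag is inferred from the filename (``lh.*``/``rh.*``) unless
    given explicitly.
    """
    path = Path(path)
    hemi = _infer_hemisphere(path, hemisphere)
    try:
        if fmt == "freesurfer":
            vertices, faces = nib.freesurfer.io.read_geometry(str(path))
        elif fmt == "gifti":
            img = nib.load(str(path))
            vertices = faces = None
            for da in img.darrays:
                if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                    vertices = da.data
                elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                    faces = da.data
            if vertices is None or faces is None:
                raise FormatError(f"{path}: GIfTI file lacks POINTSET/TRIANGLE arrays")
        else:
            raise FormatError(f"unknown surface format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-typed with context
        raise FormatError(f"{path}: failed to parse as {fmt} surface: {exc}") from exc
    return CorticalSurface(vertices=vertices, faces=faces, hemisphere=hemi)


def write_surface(surface: CorticalSurface, path, fmt: str = "freesurfer") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "freesurfer":
        nib.freesurfer.io.write_geometry(
            str(path), surface.vertices.astype(np.float32), surface.faces.astype(np.int32)
        )
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    surface.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    surface.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        raise FormatError(f"unknown surface format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# morph maps
# ---------------------------------------------------------------------------

def _check_curv_size(path: Path) -> None:
    """Reject truncated curv files: header-declared count vs actual byte size."""
    raw = path.read_bytes()
    if len(raw) < 15:
        raise FormatError(f"{path}: curv file truncated at byte {len(raw)} (header incomplete)")
    if raw[:3] == b"\xff\xff\xff":  # "new"-format magic
        vnum = int.from_bytes(raw[3:7], "big")
        expected = 15 + 4 * vnum
        if len(raw) < expected:
            raise FormatError(
                f"{path}: curv file truncated at byte {len(raw)}, "
                f"expected {expected} for {vnum} vertices"
            )


def read_morph(path, fmt: str = "freesurfer_curv", n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex scalar map (FreeSurfer curv format or GIfTI)."""
    path = Path(path)
    try:
        if fmt == "freesurfer_curv":
            _check_curv_size(path)
            arr = nib.freesurfer.io.read_morph_data(str(path))
        elif fmt == "gifti":
            img = nib.load(str(path))
            arr = img.darrays[0].data
        else:
            raise FormatError(f"unknown morph format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: failed to parse as {fmt} morph map: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64).ravel()
    if not np.isfinite(arr).all():
        raise FormatError(f"{path}: morph map contains non-finite values")
    if n_vertices is not None and arr.size != n_vertices:
        raise DimensionError(f"{path}: morph map has {arr.size} values, surface has {n_vertices}")
    return arr


def write_morph(values: np.ndarray, path, fmt: str = "freesurfer_curv") -> Path:
    values = np.asarray(values, dtype=np.float64).ravel()
    if not np.isfinite(values).all():
        raise FormatError("refusing to write non-finite morph values")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "freesurfer_curv":
        nib.freesurfer.io.write_morph_data(str(path), values.astype(np.float32))
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[nib.gifti.GiftiDataArray(values.astype(np.float32), intent="NIFTI_INTENT_NONE")]
        )
        nib.save(img, str(path))
    else:
        raise FormatError(f"unknown morph format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# plain-text index lists
# ---------------------------------------------------------------------------

def read_index_list(path) -> np.ndarray:
    """Read a hinge vertex-index list (one index per line, ``#`` comments).

    An optional ``index_base=<0|1>`` header line declares the on-disk base;
    indices are returned 0-based.
    """
    path = Path(path)
    base = 0
    out: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("index_base"):
            try:
                base = int(line.split("=", 1)[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad index_base header {raw!r}") from exc
            if base not in (0, 1):
                raise FormatError(f"{path}:{lineno}: index_base must be 0 or 1, got {base}")
            continue
        try:
            out.append(int(line))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not a vertex index: {raw!r}") from exc
    idx = np.asarray(out, dtype=np.int64) - base
    if idx.size and idx.min() < 0:
        raise FormatError(f"{path}: negative vertex index after applying index_base={base}")
    return idx


def write_index_list(indices: np.ndarray, path, comment: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("index_base=0")
    lines.extend(str(int(i)) for i in np.asarray(indices).ravel())
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# centroid tables / outputs
# ---------------------------------------------------------------------------

CENTROID_COLUMNS = ["hemisphere", "x", "y", "z", "cluster_size"]


def write_centroid_csv(centroids: np.ndarray, cluster_sizes, hemisphere: str, path) -> Path:
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    df = pd.DataFrame(
        {
            "hemisphere": [hemisphere] * len(centroids),
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "z": centroids[:, 2],
            "cluster_size": np.asarray(cluster_sizes, dtype=np.int64).ravel(),
        },
        columns=CENTROID_COLUMNS,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_centroid_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: centroid CSV missing columns {missing}")
    return df


def write_outputs(labels, centroid_set, out_dir, prefix: str = "lh", metrics: dict | None = None) -> dict:
    """Write per-vertex labels, centroid table and optional metrics report.

    Labels go out twice: as a FreeSurfer curv-format 0/1 overlay and as a
    plain-text vertex-index list. Centroids go to CSV with columns
    hemisphere,x,y,z,cluster_size.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    labels = np.asarray(labels).astype(np.float64).ravel()
    written = {}
    written["overlay"] = write_morph(labels, out_dir / f"{prefix}.hinge_region")
    written["index_list"] = write_index_list(
        np.flatnonzero(labels > 0.5), out_dir / f"{prefix}.hinge_region.txt",
        comment="predicted 3-hinge region vertices",
    )
    if centroid_set is not None:
        written["centroids"] = write_centroid_csv(
            centroid_set.centroids, centroid_set.cluster_sizes, prefix,
            out_dir / f"{prefix}.centroids.csv",
        )
    if metrics is not None:
        p = out_dir / f"{prefix}.metrics.json"
        p.write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
        written["metrics"] = p
    return written


def warn_empty(what: str) -> None:
    warnings.warn(f"{what} is empty", stacklevel=3)
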