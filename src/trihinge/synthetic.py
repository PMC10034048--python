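"""Seeded synthetic cortical sheets with ground-truth gyral hinges.

The generator produces a 2.5-D height-field sheet: a regular vertex lattice
whose z-coordinate rises along a planar *ridge skeleton* (the gyral crest
network). Triple junctions of the skeleton — nodes where three or more
crests meet — are the ground-truth 3-hinges; points sampled along crest
lines between junctions are 2-hinges. Morphometry maps are statistically
coupled to ridge geometry the way real cortical maps are to gyri: sulcal
depth is lowest (most negative) on crests, curvature changes sign between
crest and fundus, and the cortex is thicker on gyral crests.

A flat sheet rather than a closed brain-like surface is used deliberately:
every downstream operation (KNN aggregation, spherical region expansion,
blocking, mean shift) depends only on local geometry, and on a sheet the
ground truth is exact and analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree

from .errors import ConfigError
from .io import CorticalSurface, HingeAnnotation, MorphMaps

__all__ = [
    "SynthConfig",
    "Skeleton",
    "SyntheticSubject",
    "CohortMember",
    "generate_subject",
    "generate_cohort",
    "cohort_manifest",
    "skeleton_junctions",
]

DEFAULT_COUPLING = {
    "sulc": 1.0,        # sulc = -sulc_coeff * height + noise
    "curv": 1.0,        # curv = curv_coeff * mean curvature of the height field
    "thick_base": 2.5,  # mm, fossa cortical thickness
    "thick_gain": 0.6,  # mm added at full ridge height (gyri are thicker)
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic subject (one hemisphere sheet).

    ``grid_shape`` is the vertex lattice (rows, cols) at ``spacing`` mm;
    ``ridge_pattern`` selects the crest-network topology; ``n_cells`` the
    target number of ridge cells (gyral "blocks" enclosed by crests);
    ``ridge_height`` the gyral amplitude in mm; ``ridge_width`` the Gaussian
    half-width of a crest in mm; ``noise_sd`` the vertex jitter and map noise
    scale in mm. Identical configs generate bitwise-identical subjects.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (256, 256)
    spacing: float = 1.0
    ridge_pattern: str = "hex_lattice"
    n_cells: int = 24
    ridge_height: float = 5.0
    ridge_width: float = 2.5
    noise_sd: float = 0.25
    margin: float = 8.0
    morph_coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ConfigError(f"grid_shape must be at least 2x2, got {self.grid_shape}")
        if self.spacing <= 0:
            raise ConfigError("spacing must be > 0")
        if self.ridge_height < 0 or self.noise_sd < 0 or self.ridge_width <= 0:
            raise ConfigError("ridge_height/noise_sd must be >= 0 and ridge_width > 0")
        if self.ridge_pattern not in ("hex_lattice", "tri_lattice", "random_voronoi"):
            raise ConfigError(f"unknown ridge_pattern {self.ridge_pattern!r}")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        width = (cols - 1) * self.spacing
        height = (rows - 1) * self.spacing
        area = width * height
        a = np.sqrt(2.0 * area / (np.sqrt(3.0) * self.n_cells))
        if a < 4.0 * self.spacing:
            raise ConfigError(
                f"grid {self.grid_shape} at spacing {self.spacing} is too small to host "
                f"{self.n_cells} ridge cells (cell pitch {a:.2f} mm < {4 * self.spacing} mm)"
            )
        if 2.0 * self.margin >= min(width, height):
            raise ConfigError("margin leaves no interior region")


@dataclass
class Skeleton:
    """Planar ridge-crest graph: node coordinates (mm) and undirected edges."""

    nodes: np.ndarray  # (N, 2) float
    edges: np.ndarray  # (E, 2) int, indices into nodes

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def segments(self) -> np.ndarray:
        """Edge geometry as an (E, 2, 2) array of endpoint coordinates."""
        if not len(self.edges):
            return np.zeros((0, 2, 2))
        return self.nodes[self.edges]


def skeleton_junctions(skel: Skeleton) -> np.ndarray:
    """Indices of skeleton nodes where >= 3 crest edges meet (triple junctions)."""
    return np.flatnonzero(skel.degrees() >= 3)


@dataclass
class SyntheticSubject:
    surface: CorticalSurface
    maps: MorphMaps
    annotation: HingeAnnotation
    skeleton: Skeleton
    height: np.ndarray          # noiseless ridge height field per vertex
    dist_to_skeleton: np.ndarray
    config: SynthConfig

    def astuple(self):
        return self.surface, self.maps, self.annotation


@dataclass(frozen=True)
class CohortMember:
    subject_id: str
    gender: int
    config: SynthConfig

    def generate(self) -> SyntheticSubject:
        return generate_subject(self.config)


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------

def _clip_segments(segments: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Liang-Barsky clip of 2-D segments to the axis-aligned box [lo, hi]."""
    kept = []
    for p0, p1 in segments:
        d = p1 - p0
        t0, t1 = 0.0, 1.0
        ok = True
        for axis in range(2):
            if abs(d[axis]) < 1e-12:
                if p0[axis] < lo[axis] or p0[axis] > hi[axis]:
                    ok = False
                    break
                continue
            ta = (lo[axis] - p0[axis]) / d[axis]
            tb = (hi[axis] - p0[axis]) / d[axis]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
            if t0 > t1:
                ok = False
                break
        if ok and t1 - t0 > 1e-9:
            kept.append((p0 + t0 * d, p0 + t1 * d))
    return np.asarray(kept).reshape(-1, 2, 2)


def _segments_to_graph(segments: np.ndarray, tol: float = 1e-6) -> Skeleton:
    """Merge shared segment endpoints into graph nodes."""
    if not len(segments):
        return Skeleton(np.zeros((0, 2)), np.zeros((0, 2), dtype=np.int64))
    pts = segments.reshape(-1, 2)
    key = np.round(pts / tol).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    # representative coordinate per node: first occurrence
    order = np.argsort(inv, kind="stable")
    first = np.zeros(inv.max() + 1, dtype=np.int64)
    seen = np.zeros(inv.max() + 1, dtype=bool)
    for i in order:
        if not seen[inv[i]]:
            seen[inv[i]] = True
            first[inv[i]] = i
    nodes = pts[first]
    edges = inv.reshape(-1, 2)
    edges = edges[edges[:, 0] != edges[:, 1]]
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    return Skeleton(nodes, edges)


def _hex_seeds(width: float, height: float, a: float, rng: np.random.Generator) -> np.ndarray:
    """Triangular-lattice seed points (whose Voronoi cells are hexagons)."""
    dy = a * np.sqrt(3.0) / 2.0
    xs, ys = [], []
    row = 0
    y = -2.0 * a
    while y < height + 2.0 * a:
        offset = 0.5 * a if row % 2 else 0.0
        x = -2.0 * a + offset
        while x < width + 2.0 * a:
            xs.append(x)
            ys.append(y)
            x += a
        y += dy
        row += 1
    pts = np.column_stack([xs, ys])
    # break exact co-circularity for the Voronoi construction
    pts += rng.normal(0.0, 1e-4 * a, pts.shape)
    return pts


def _random_seeds(width: float, height: float, n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    """Blue-noise-ish random seeds with a minimum pitch, plus a closing ring."""
    pts: list[np.ndarray] = []
    min_d = 0.55 * a
    attempts = 0
    while len(pts) < n and attempts < 50 * n:
        cand = rng.uniform([0, 0], [width, height])
        if all(np.hypot(*(cand - p)) >= min_d for p in pts):
            pts.append(cand)
        attempts += 1
    inner = np.asarray(pts)
    ring = []
    for x, y in inner:
        for rx, ry in ((-x, y), (2 * width - x, y), (x, -y), (x, 2 * height - y)):
            ring.append((rx, ry))
    return np.vstack([inner, np.asarray(ring)])


def _tri_lattice_skeleton(width: float, height: float, a: float) -> np.ndarray:
    """Segments of a triangular lattice (junction degree 6)."""
    dy = a * np.sqrt(3.0) / 2.0
    nodes = {}
    rows = int(height / dy) + 5
    cols = int(width / a) + 5
    for r in range(-2, rows):
        for c in range(-2, cols):
            x = c * a + (0.5 * a if r % 2 else 0.0) - a
            y = r * dy - a
            nodes[(r, c)] = (x, y)
    segs = []
    for (r, c), p in nodes.items():
        for nb in ((r, c + 1), (r + 1, c), (r + 1, c + 1 if r % 2 else c - 1)):
            q = nodes.get(nb)
            if q is not None:
                segs.append((p, q))
    return np.asarray(segs)


def build_skeleton(cfg: SynthConfig, rng: np.random.Generator) -> Skeleton:
    """Construct the ridge-crest graph clipped to the sheet's interior box."""
    rows, cols = cfg.grid_shape
    width = (cols - 1) * cfg.spacing
    height = (rows - 1) * cfg.spacing
    area = width * height
    a = np.sqrt(2.0 * area / (np.sqrt(3.0) * cfg.n_cells))
    lo = np.array([cfg.margin, cfg.margin])
    hi = np.array([width - cfg.margin, height - cfg.margin])

    if cfg.ridge_pattern == "tri_lattice":
        segs = _tri_lattice_skeleton(width, height, a)
    else:
        if cfg.ridge_pattern == "hex_lattice":
            seeds = _hex_seeds(width, height, a, rng)
        else:
            seeds = _random_seeds(width, height, cfg.n_cells, a, rng)
        vor = Voronoi(seeds)
        segs = []
        for (i, j) in vor.ridge_vertices:
            if i < 0 or j < 0:
                continue
            segs.append((vor.vertices[i], vor.vertices[j]))
        segs = np.asarray(segs)
    clipped = _clip_segments(segs, lo, hi)
    return _segments_to_graph(clipped)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _dist_to_segments(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each 2-D point to a set of segments."""
    n = len(points)
    if not len(segments):
        return np.full(n, np.inf)
    best = np.full(n, np.inf)
    for p0, p1 in segments:
        d = p1 - p0
        l2 = float(d @ d)
        if l2 < 1e-18:
            dist = np.hypot(points[:, 0] - p0[0], points[:, 1] - p0[1])
        else:
            t = np.clip(((points - p0) @ d) / l2, 0.0, 1.0)
            proj = p0 + t[:, None] * d
            dist = np.hypot(points[:, 0] - proj[:, 0], points[:, 1] - proj[:, 1])
        np.minimum(best, dist, out=best)
    return best


def _grid_faces(rows: int, cols: int) -> np.ndarray:
    r, c = np.meshgrid(np.arange(rows - 1), np.arange(cols - 1), indexing="ij")
    v = (r * cols + c).ravel()
    f1 = np.column_stack([v, v + 1, v + cols])
    f2 = np.column_stack([v + 1, v + cols + 1, v + cols])
    return np.vstack([f1, f2]).astype(np.int64)


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One-third of incident triangle areas per vertex (barycentric split)."""
    p0, p1, p2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    out = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(out, faces[:, k], tri_area / 3.0)
    return out


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def generate_subject(cfg: SynthConfig, hemisphere: str = "lh") -> SyntheticSubject:
    """Generate one synthetic sheet: surface, morph maps and hinge ground truth.

    With ``ridge_height == 0`` the sheet is flat and carries no hinges; the
    annotation is empty. Hinge labels and centroids always come from the
    noiseless skeleton, so the planted junction count is invariant to
    ``noise_sd``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    sp = cfg.spacing
    xs = np.arange(cols) * sp
    ys = np.arange(rows) * sp
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    # vertex id = row * cols + col, row-major
    pts2d = np.column_stack([gx.ravel(), gy.ravel()])
    n = rows * cols

    skel = build_skeleton(cfg, rng)
    if cfg.ridge_height > 0 and len(skel.edges):
        dist = _dist_to_segments(pts2d, skel.segments())
        height = cfg.ridge_height * np.exp(-(dist**2) / (2.0 * cfg.ridge_width**2))
    else:
        dist = np.full(n, np.inf)
        height = np.zeros(n)
        skel = Skeleton(np.zeros((0, 2)), np.zeros((0, 2), dtype=np.int64))

    z = height + rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else height.copy()
    vertices = np.column_stack([pts2d, z])
    faces = _grid_faces(rows, cols)
    surface = CorticalSurface(vertices=vertices, faces=faces, hemisphere=hemisphere)

    maps = _morph_maps(cfg, rng, surface, height, rows, cols)
    annotation = _annotate(cfg, skel, rows, cols, height)
    return SyntheticSubject(
        surface=surface, maps=maps, annotation=annotation, skeleton=skel,
        height=height, dist_to_skeleton=dist, config=cfg,
    )


def _morph_maps(cfg, rng, surface, height, rows, cols) -> MorphMaps:
    cp = {**DEFAULT_COUPLING, **cfg.morph_coupling}
    noise = cfg.noise_sd
    n = rows * cols
    hmax = cfg.ridge_height if cfg.ridge_height > 0 else 1.0

    sulc = -cp["sulc"] * height
    if noise > 0:
        sulc = sulc + rng.normal(0.0, noise, n)

    # mean curvature of the noiseless height field: positive on crests
    h2 = height.reshape(rows, cols)
    lap = ndimage.laplace(h2, mode="nearest") / (cfg.spacing**2)
    curv = -0.5 * cp["curv"] * lap.ravel()
    if noise > 0:
        curv = curv + rng.normal(0.0, 0.02 * noise, n)

    thick = cp["thick_base"] + cp["thick_gain"] * (height / hmax)
    if noise > 0:
        thick = thick + rng.normal(0.0, 0.05 * noise, n)
    thick = np.clip(thick, 0.1, None)

    area = _vertex_areas(surface.vertices, surface.faces)
    vol = area * thick
    return MorphMaps({"sulc": sulc, "curv": curv, "thick": thick, "area": area, "vol": vol})


def _nearest_grid_vertex(xy: np.ndarray, cfg: SynthConfig, rows: int, cols: int) -> int:
    c = int(np.clip(round(xy[0] / cfg.spacing), 0, cols - 1))
    r = int(np.clip(round(xy[1] / cfg.spacing), 0, rows - 1))
    return r * cols + c


def _annotate(cfg, skel: Skeleton, rows, cols, height) -> HingeAnnotation:
    if cfg.ridge_height == 0 or not len(skel.edges):
        return HingeAnnotation(
            two_hinge_idx=np.zeros(0, dtype=np.int64),
            three_hinge_idx=np.zeros(0, dtype=np.int64),
            three_hinge_centroids=np.zeros((0, 3)),
        )
    jn = skeleton_junctions(skel)
    jxy = skel.nodes[jn]
    three_idx, centroids, seen = [], [], set()
    for p in jxy:
        centroids.append((p[0], p[1], cfg.ridge_height))  # exact: crest height at d=0
        v = _nearest_grid_vertex(p, cfg, rows, cols)
        if v in seen:
            continue  # two junctions can share a nearest vertex; keep one index
        seen.add(v)
        three_idx.append(v)
    three_set = set(three_idx)

    excl = 1.5 * cfg.spacing
    jtree = cKDTree(jxy) if len(jxy) else None
    two_idx, seen2 = [], set()
    for p0, p1 in skel.segments():
        length = float(np.hypot(*(p1 - p0)))
        if length < cfg.spacing:
            continue
        n_steps = int(length / cfg.spacing)
        for s in range(n_steps + 1):
            q = p0 + (s * cfg.spacing / length) * (p1 - p0)
            if jtree is not None and jtree.query(q)[0] <= excl:
                continue
            v = _nearest_grid_vertex(q, cfg, rows, cols)
            if v in seen2 or v in three_set:
                continue
            seen2.add(v)
            two_idx.append(v)
    return HingeAnnotation(
        two_hinge_idx=np.asarray(sorted(two_idx), dtype=np.int64),
        three_hinge_idx=np.asarray(three_idx, dtype=np.int64),
        three_hinge_centroids=np.asarray(centroids, dtype=np.float64).reshape(-1, 3),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _derive_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 100003 + 7919 * index + 13) % (2**31))


def generate_cohort(n_subjects: int, base_cfg: SynthConfig, gender_effect: float = 0.0) -> list[CohortMember]:
    """Plan a cohort with alternating genders and a planted ridge-height shift.

    Subjects alternate gender (0, 1, 0, 1, ...); gender-1 subjects get
    ``ridge_height + gender_effect``, emulating more prominent gyral hinges in
    one group. Per-subject seeds are derived deterministically from the base
    seed; members are lazy — call :meth:`CohortMember.generate`.
    """
    if n_subjects < 2:
        raise ConfigError("a cohort needs at least 2 subjects")
    base_cfg.validate()
    members = []
    for i in range(n_subjects):
        gender = i % 2
        cfg = replace(
            base_cfg,
            seed=_derive_seed(base_cfg.seed, i),
            ridge_height=base_cfg.ridge_height + (gender_effect if gender == 1 else 0.0),
        )
        members.append(CohortMember(subject_id=f"s{i:03d}", gender=gender, config=cfg))
    return members


def cohort_manifest(members: list[CohortMember], paths: dict[str, str] | None = None) -> pd.DataFrame:
    rows = [
        {
            "subject_id": m.subject_id,
            "gender": m.gender,
            "seed": m.config.seed,
            "path": (paths or {}).get(m.subject_id, ""),
        }
        for m in members
    ]
    return pd.DataFrame(rows, columns=["subject_id", "gender", "seed", "path"])


def write_subject(subject: SyntheticSubject, out_dir, prefix: str = "lh") -> dict:
    """Write a synthetic subject in the same formats the real-data path reads."""
    from . import io as tio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {"surface": tio.write_surface(subject.surface, out_dir / f"{prefix}.surf")}
    for name in subject.maps.names():
        written[name] = tio.write_morph(subject.maps[name], out_dir / f"{prefix}.{name}")
    written["two_hinge"] = tio.write_index_list(
        subject.annotation.two_hinge_idx, out_dir / f"{prefix}.2hinge.txt", comment="2-hinge vertices"
    )
    written["three_hinge"] = tio.write_index_list(
        subject.annotation.three_hinge_idx, out_dir / f"{prefix}.3hinge.txt", comment="3-hinge vertices"
    )
    cent = subject.annotation.three_hinge_centroids
    written["centroids"] = tio.write_centroid_csv(
        cent, np.ones(len(cent), dtype=int), prefix, out_dir / f"{prefix}.true_centroids.csv"
    )
    return written
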