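"""Synthetic cortical-surface stand-ins: icospheres, graph-Voronoi
parcellations, and parcel-structured multi-channel features.

Real inputs are FreeSurfer meshes resampled to a subdivided icosahedron
(fsaverage5 is subdivision order 5: 10,242 vertices), six per-vertex
morphological channels, and a manual parcellation.  The generator mimics
exactly that shape of data: a unit icosphere mesh, a hop-distance Voronoi
parcellation from seeded vertices, and features that are per-parcel means
plus spatially smoothed Gaussian noise — so the entire pipeline can be
exercised and benchmarked with no imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .graph import BrainGraph, averaging_operator, build_adjacency
from .io import Parcellation, PerVertexScalar, SurfaceMesh

__all__ = [
    "SyntheticSpec",
    "CHANNEL_NAMES",
    "Subject",
    "generate_icosphere",
    "generate_parcellation",
    "generate_features",
    "vertex_area",
    "make_dataset",
    "make_label_table",
    "parcellation_of",
]

# named after the six FreeSurfer morphological channels the model consumes
CHANNEL_NAMES = ("area", "curv", "jacobian", "sulc", "thickness", "volume")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    signal_strength is the sd (in noise-sd units once noise_sd = 1) of the
    per-parcel channel means; noise_sd scales the vertex-level Gaussian
    noise, which is smoothed ``smoothing_steps`` times with the
    row-stochastic mesh-averaging operator so it is spatially correlated
    like real curvature maps.  subject_jitter perturbs both the parcel
    seeds (Poisson-many random hops) and the parcel means across subjects.
    """

    level: int = 4
    n_parcels: int = 8
    n_channels: int = 6
    signal_strength: float = 3.0
    noise_sd: float = 1.0
    smoothing_steps: int = 2
    subject_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.level < 0 or self.n_parcels < 1 or self.n_channels < 1:
            raise ValueError("bad synthetic spec")
        if min(self.signal_strength, self.noise_sd,
               self.subject_jitter) < 0 or self.smoothing_steps < 0:
            raise ValueError("scales must be >= 0")


@dataclass
class Subject:
    """One subject: shared-resolution graph, features and ground truth."""

    id: str
    mesh: SurfaceMesh
    graph: BrainGraph
    features: np.ndarray       # (N, C)
    labels: np.ndarray         # (N,) class indices
    label_table: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.graph.n_vertices
        if len(self.features) != n or len(self.labels) != n:
            raise ValueError("subject components disagree on vertex count")


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return verts / np.linalg.norm(verts, axis=1, keepdims=True), faces


def generate_icosphere(level: int) -> SurfaceMesh:
    """Subdivide the regular icosahedron ``level`` times onto the unit
    sphere: 10·4^L + 2 vertices, 20·4^L faces (level 5 = 10,242 vertices,
    the fsaverage5 resolution).  Midpoints are deduplicated by exact
    index-pair keys, so the construction is deterministic.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(level):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                p = verts_list[i] + verts_list[j]
                verts_list.append(p / np.linalg.norm(p))
                midpoint[key] = len(verts_list) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    return SurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def generate_parcellation(mesh: SurfaceMesh, n_parcels: int,
                          seed: int | np.random.Generator,
                          graph: BrainGraph | None = None,
                          seed_vertices: np.ndarray | None = None) -> np.ndarray:
    """Graph-geodesic (hop-distance) Voronoi labels from random seeds.

    Ties between equidistant seeds go to the lowest seed index, so every
    parcel is a connected, deterministic vertex set.
    """
    n = mesh.n_vertices
    if n_parcels > n:
        raise ValueError("more parcels than vertices")
    graph = graph or build_adjacency(mesh)
    if seed_vertices is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        seed_vertices = rng.choice(n, size=n_parcels, replace=False)
    seed_vertices = np.asarray(seed_vertices, dtype=np.int64)
    dist = dijkstra(graph.adjacency, indices=seed_vertices, unweighted=True)
    return np.argmin(dist, axis=0).astype(np.int64)  # argmin ties -> lowest index


def make_label_table(n_parcels: int) -> dict:
    """Distinct non-black colors so annot round-trips are exact."""
    table = {}
    for k in range(n_parcels):
        r = (37 * (k + 1)) % 255 + 1
        g = (101 * (k + 1)) % 256
        b = (197 * (k + 1)) % 256
        table[k] = (f"parcel-{k:02d}", (r, g, b), k)
    return table


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _smooth(graph: BrainGraph, x: np.ndarray, steps: int) -> np.ndarray:
    op = averaging_operator(graph)
    for _ in range(steps):
        x = op @ x
    return x


def generate_features(graph: BrainGraph, labels: np.ndarray,
                      spec: SyntheticSpec,
                      rng: np.random.Generator | None = None,
                      parcel_means: np.ndarray | None = None) -> np.ndarray:
    """X[i, c] = μ(label_i, c) + smoothed ε[i, c].

    Parcel means are N(0, signal_strength²) draws (one per parcel and
    channel); noise is N(0, noise_sd²) smoothed by the row-stochastic
    averaging operator, giving the local spatial correlation real
    morphological maps have.
    """
    rng = rng or np.random.default_rng(spec.seed)
    k = int(labels.max()) + 1
    if parcel_means is None:
        parcel_means = spec.signal_strength * rng.standard_normal((k, spec.n_channels))
    noise = spec.noise_sd * rng.standard_normal((graph.n_vertices, spec.n_channels))
    noise = _smooth(graph, noise, spec.smoothing_steps)
    return parcel_means[labels] + noise


def vertex_area(mesh: SurfaceMesh) -> PerVertexScalar:
    """Per-vertex surface area: one third of each incident triangle's area,
    so vertex areas sum exactly to the total mesh area."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(areas, f[:, col], tri_area / 3.0)
    return PerVertexScalar("area", areas)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _jitter_seeds(graph: BrainGraph, seeds: np.ndarray, hops: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    adj = graph.adjacency
    out = seeds.copy()
    for idx, (s, h) in enumerate(zip(seeds, hops)):
        v = int(s)
        for _ in range(int(h)):
            nbrs = adj.indices[adj.indptr[v]:adj.indptr[v + 1]]
            v = int(rng.choice(nbrs))
        out[idx] = v
    return out


def make_dataset(n_subjects: int, spec: SyntheticSpec) -> list[Subject]:
    """A cohort sharing one template parcellation, each subject's parcel
    seeds and means perturbed by ``subject_jitter``, features redrawn."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    mesh = generate_icosphere(spec.level)
    graph = build_adjacency(mesh)
    root = np.random.SeedSequence(spec.seed)
    template_rng = np.random.default_rng(root.spawn(1)[0])
    template_seeds = template_rng.choice(mesh.n_vertices, size=spec.n_parcels,
                                         replace=False)
    template_means = spec.signal_strength * template_rng.standard_normal(
        (spec.n_parcels, spec.n_channels))
    table = make_label_table(spec.n_parcels)
    subjects = []
    for s, child in enumerate(root.spawn(1)[0].spawn(n_subjects)):
        rng = np.random.default_rng(child)
        hops = rng.poisson(spec.subject_jitter, size=spec.n_parcels)
        seeds = _jitter_seeds(graph, template_seeds, hops, rng)
        labels = generate_parcellation(mesh, spec.n_parcels, rng, graph=graph,
                                       seed_vertices=seeds)
        means = template_means + 0.1 * spec.subject_jitter * rng.standard_normal(
            template_means.shape)
        feats = generate_features(graph, labels, spec, rng=rng,
                                  parcel_means=means)
        subjects.append(Subject(f"sub-{s:03d}", mesh, graph, feats, labels, table))
    return subjects


def parcellation_of(subject: Subject) -> Parcellation:
    return Parcellation(subject.labels, subject.label_table)
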