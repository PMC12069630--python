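"""FreeSurfer surface / curv / annot I/O and the core mesh containers.

Supports the modern magic-tagged dialects used by fsaverage templates and
the Mindboggle distribution: binary triangle surfaces (magic 0xFFFFFE),
new-format per-vertex curv files (magic 0xFFFFFF) and annot label files
with an embedded color table.  All multi-byte values are big-endian; the
obsolete quad surface and old curv dialects are rejected.

Vertex indices are 0-based throughout (the on-disk formats already are).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceMesh",
    "PerVertexScalar",
    "Parcellation",
    "read_surface",
    "write_surface",
    "read_curv",
    "write_curv",
    "read_annot",
    "write_annot",
]

_TRIANGLE_MAGIC = 0xFFFFFE
_QUAD_MAGIC = 0xFFFFFF  # same 3 bytes as new-curv, context disambiguates
_CURV_MAGIC = 0xFFFFFF
_IGNORE = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangular surface mesh: vertex coordinates (mm) and faces."""

    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray     # (M, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        n = len(self.vertices)
        if n < 3 or len(self.faces) < 1:
            raise ValueError("mesh needs at least 3 vertices and 1 face")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValueError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class PerVertexScalar:
    """One named per-vertex morphological feature (thickness, sulc, ...)."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in scalar '{self.name}'")


@dataclass
class Parcellation:
    """Per-vertex region labels with a color/name table.

    ``labels`` holds contiguous class indices ``0..K-1``; vertices without
    a table entry carry ``ignore_index``.  ``label_table`` maps each class
    index to ``(name, (r, g, b), structure_id)``.
    """

    labels: np.ndarray
    label_table: dict = field(default_factory=dict)
    ignore_index: int = _IGNORE

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        used = set(np.unique(self.labels)) - {self.ignore_index}
        if not used <= set(self.label_table):
            raise ValueError("labels reference classes missing from label_table")

    @property
    def n_classes(self) -> int:
        return len(self.label_table)


def _pack_rgb(r: int, g: int, b: int) -> int:
    return int(r) + (int(g) << 8) + (int(b) << 16)


# ---------------------------------------------------------------------------
# binary helpers (big-endian throughout)
# ---------------------------------------------------------------------------

def _read_exact(f, n: int, what: str) -> bytes:
    buf = f.read(n)
    if len(buf) != n:
        raise ValueError(f"corrupt {what}: truncated payload")
    return buf


def _read_int3(f, what: str) -> int:
    b = _read_exact(f, 3, what)
    return (b[0] << 16) + (b[1] << 8) + b[2]


def _write_int3(f, value: int) -> None:
    f.write(bytes([(value >> 16) & 0xFF, (value >> 8) & 0xFF, value & 0xFF]))


# ---------------------------------------------------------------------------
# triangle surface
# ---------------------------------------------------------------------------

def read_surface(path) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface."""
    with open(path, "rb") as f:
        magic = _read_int3(f, "surface file")
        if magic == _QUAD_MAGIC:
            raise ValueError("unrecognized surface format: quad files unsupported")
        if magic != _TRIANGLE_MAGIC:
            raise ValueError("unrecognized surface format")
        f.readline()  # creation comment
        f.readline()  # trailing newline
        head = _read_exact(f, 8, "surface file")
        n_vert, n_face = struct.unpack(">2i", head)
        if n_vert <= 0 or n_face <= 0:
            raise ValueError("corrupt surface file: bad counts")
        vbuf = _read_exact(f, 12 * n_vert, "surface file")
        fbuf = _read_exact(f, 12 * n_face, "surface file")
    vertices = np.frombuffer(vbuf, dtype=">f4").reshape(n_vert, 3).astype(np.float64)
    faces = np.frombuffer(fbuf, dtype=">i4").reshape(n_face, 3).astype(np.int64)
    return SurfaceMesh(vertices, faces)


def write_surface(mesh: SurfaceMesh, path) -> None:
    """Write a FreeSurfer binary triangle surface (deterministic bytes)."""
    mesh.validate()
    with open(path, "wb") as f:
        _write_int3(f, _TRIANGLE_MAGIC)
        f.write(b"created by adgcn\n\n")
        f.write(struct.pack(">2i", mesh.n_vertices, mesh.n_faces))
        f.write(mesh.vertices.astype(">f4").tobytes())
        f.write(mesh.faces.astype(">i4").tobytes())


# ---------------------------------------------------------------------------
# curv (new format only)
# ---------------------------------------------------------------------------

def read_curv(path, name: str | None = None,
              expect_n: int | None = None) -> PerVertexScalar:
    """Read a new-format FreeSurfer curv file of per-vertex scalars."""
    with open(path, "rb") as f:
        magic = _read_int3(f, "curv file")
        if magic != _CURV_MAGIC:
            raise ValueError("unrecognized curv format (old dialect or byte-swapped)")
        n_vert, _n_face, vals_per = struct.unpack(">3i", _read_exact(f, 12, "curv file"))
        if n_vert <= 0 or vals_per != 1:
            raise ValueError("corrupt curv file: bad header")
        buf = _read_exact(f, 4 * n_vert, "curv file")
    values = np.frombuffer(buf, dtype=">f4").astype(np.float64)
    if expect_n is not None and n_vert != expect_n:
        raise ValueError(f"curv length {n_vert} does not match expected {expect_n}")
    if name is None:
        import os
        name = os.path.basename(str(path)).split(".")[-1]
    return PerVertexScalar(name, values)


def write_curv(scalar: PerVertexScalar, path) -> None:
    with open(path, "wb") as f:
        _write_int3(f, _CURV_MAGIC)
        f.write(struct.pack(">3i", len(scalar.values), 0, 1))
        f.write(scalar.values.astype(">f4").tobytes())


# ---------------------------------------------------------------------------
# annot
# ---------------------------------------------------------------------------

def read_annot(path) -> Parcellation:
    """Read a FreeSurfer annot file, remapping packed colors to class ids.

    Classes are numbered ``0..K-1`` in color-table order; any vertex whose
    packed annotation value matches no table entry gets ``ignore_index``.
    """
    import os
    fsize = os.path.getsize(path)
    with open(path, "rb") as f:
        (n_vert,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
        if n_vert <= 0 or 4 + 8 * n_vert > fsize:
            raise ValueError("corrupt annot file: implausible vertex count "
                             "(byte-swapped input?)")
        pairs = np.frombuffer(_read_exact(f, 8 * n_vert, "annot file"),
                              dtype=">i4").reshape(n_vert, 2)
        tag_bytes = f.read(4)
        if len(tag_bytes) < 4 or struct.unpack(">i", tag_bytes)[0] != 1:
            raise ValueError("annot without colortable unsupported")
        (n_entries,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
        table = {}
        if n_entries > 0:  # version-1 table
            (slen,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
            _read_exact(f, slen, "annot file")  # original table filename
            for i in range(n_entries):
                (slen,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
                name = _read_exact(f, slen, "annot file").rstrip(b"\0").decode()
                r, g, b, _t = struct.unpack(">4i", _read_exact(f, 16, "annot file"))
                table[i] = (name, (r, g, b), i)
        else:  # version-2 table
            version = -n_entries
            if version != 2:
                raise ValueError(f"unsupported annot colortable version {version}")
            (_max_struct,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
            (slen,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
            _read_exact(f, slen, "annot file")
            (n_to_read,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
            for _ in range(n_to_read):
                # the leading int of each v2 entry is its table row index
                (idx,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
                (slen,) = struct.unpack(">i", _read_exact(f, 4, "annot file"))
                name = _read_exact(f, slen, "annot file").rstrip(b"\0").decode()
                r, g, b, _t = struct.unpack(">4i", _read_exact(f, 16, "annot file"))
                table[idx] = (name, (r, g, b), idx)
    order = np.argsort(pairs[:, 0], kind="stable")
    packed = np.empty(n_vert, dtype=np.int64)
    packed[pairs[order, 0]] = pairs[order, 1]
    by_color = {_pack_rgb(*table[i][1]): i for i in sorted(table)}
    labels = np.full(n_vert, _IGNORE, dtype=np.int64)
    for color, cls in by_color.items():
        labels[packed == color] = cls
    return Parcellation(labels, table, _IGNORE)


def write_annot(parc: Parcellation, path) -> None:
    """Write an annot file with a version-2 colortable.

    Ignored vertices are written with packed value 0 (no table entry may
    use the color (0, 0, 0) — enforced here so round-trips are exact).
    """
    colors = {}
    for cls in sorted(parc.label_table):
        name, rgb, structure = parc.label_table[cls]
        packed = _pack_rgb(*rgb)
        if packed == 0:
            raise ValueError("color (0,0,0) is reserved for unlabeled vertices")
        if packed in colors.values():
            raise ValueError("duplicate packed color in label_table")
        colors[cls] = packed
    n_vert = len(parc.labels)
    packed_vals = np.zeros(n_vert, dtype=np.int64)
    for cls, packed in colors.items():
        packed_vals[parc.labels == cls] = packed
    with open(path, "wb") as f:
        f.write(struct.pack(">i", n_vert))
        pairs = np.empty((n_vert, 2), dtype=">i4")
        pairs[:, 0] = np.arange(n_vert)
        pairs[:, 1] = packed_vals
        f.write(pairs.tobytes())
        f.write(struct.pack(">i", 1))   # colortable follows
        f.write(struct.pack(">i", -2))  # version 2
        f.write(struct.pack(">i", len(parc.label_table)))
        fname = b"adgcn.ctab\0"
        f.write(struct.pack(">i", len(fname)))
        f.write(fname)
        f.write(struct.pack(">i", len(parc.label_table)))
        for cls in sorted(parc.label_table):
            name, (r, g, b), _structure = parc.label_table[cls]
            f.write(struct.pack(">i", int(cls)))  # v2 entries carry their row index
            nb = name.encode() + b"\0"
            f.write(struct.pack(">i", len(nb)))
            f.write(nb)
            f.write(struct.pack(">4i", int(r), int(g), int(b), 0))
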