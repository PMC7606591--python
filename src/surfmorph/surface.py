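"""Triangulated-surface substrate: mesh container, FreeSurfer file IO,
vertex adjacency, per-vertex areas, and surface-based smoothing.

All vertex-wise statistics in this package run on a :class:`Mesh` — a
triangulated template surface such as FreeSurfer's fsaverage or a generated
icosphere.  Per-vertex measures travel as :class:`VertexField` objects or as
plain ``(V,)`` / ``(n_subjects, V)`` arrays.

File formats
------------
* FreeSurfer binary triangle surface (big-endian, magic ``0xFFFFFE``) via
  :func:`read_surface` / :func:`write_surface`.
* FreeSurfer "curv" / morph-data new format (magic ``0xFFFFFF``) and a plain
  one-value-per-line text format via :func:`read_vertex_field` /
  :func:`write_vertex_field`.

Decoding and encoding of the binary containers is delegated to
``nibabel.freesurfer.io``; this module validates magic numbers and shapes and
maps failures onto the package's exception hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import (
    FormatParseError,
    MeshInvariantError,
    ShapeError,
    UnsupportedFormatError,
)

_SURF_MAGIC = b"\xff\xff\xfe"
_CURV_MAGIC = b"\xff\xff\xff"

#: unit-radius icosahedron edge length; subdivision halves the edge each level
_LN2_8 = 8.0 * np.log(2.0)


@dataclass
class Mesh:
    """A triangulated surface.

    Parameters
    ----------
    coords : (V, 3) float array
        Vertex positions in mm.
    faces : (F, 3) int array
        Vertex-index triples, 0-based.
    hemisphere : {"left", "right"}
        Which hemisphere this template represents.
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MeshInvariantError("coords must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshInvariantError("faces must be (F, 3)")
        self.validate()

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self) -> None:
        """Check structural invariants; warn on multiple components."""
        V = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            raise MeshInvariantError(
                f"face indices must lie in [0, {V}); found "
                f"[{self.faces.min()}, {self.faces.max()}]"
            )
        referenced = np.zeros(V, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            orphans = np.flatnonzero(~referenced)
            raise MeshInvariantError(
                f"{orphans.size} vertices referenced by no face "
                f"(first: {orphans[:5].tolist()})"
            )
        n_comp, _ = connected_components(build_adjacency(self), directed=False)
        if n_comp > 1:
            warnings.warn(
                f"mesh has {n_comp} connected components; clusters will not "
                "span components",
                stacklevel=2,
            )

    # geometry -----------------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with col0 < col1."""
        f = self.faces
        pairs = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.coords[e[:, 0]] - self.coords[e[:, 1]], axis=1)

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.coords[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """One-ring area per vertex: one third of each incident face's area."""
        fa = self.face_areas() / 3.0
        va = np.zeros(self.n_vertices)
        for i in range(3):
            np.add.at(va, self.faces[:, i], fa)
        return va

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces


@dataclass
class VertexField:
    """A per-vertex scalar field tied to a template mesh."""

    values: np.ndarray
    feature: str = "stat"  # CT | SA | CV | stat | mask
    units: str = "unitless"  # mm | mm^2 | mm^3 | unitless

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def validate(self, mesh: Mesh | None = None) -> None:
        if mesh is not None and self.values.size != mesh.n_vertices:
            raise ShapeError(
                f"field length {self.values.size} != mesh V {mesh.n_vertices}"
            )
        if not np.isfinite(self.values).all():
            raise ShapeError("field contains non-finite values")


# ---------------------------------------------------------------------------
# mesh generation


def make_icosphere(subdivisions: int, radius: float = 100.0,
                   hemisphere: str = "left") -> Mesh:
    """Subdivided icosahedron: V = 10*4^n + 2 vertices, F = 20*4^n faces.

    Serves as a closed stand-in template for a cortical hemisphere surface.
    ``radius`` is in mm; the default 100 mm gives a surface area of the same
    order as a human cortical hemisphere.
    """
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh(np.asarray(m.vertices), np.asarray(m.faces), hemisphere)


# ---------------------------------------------------------------------------
# FreeSurfer file IO (delegated to nibabel after magic validation)


def _read_magic(path) -> bytes:
    with open(path, "rb") as fh:
        return fh.read(3)


def read_surface(path, hemisphere: str = "left") -> Mesh:
    """Read a FreeSurfer binary triangle surface."""
    import nibabel.freesurfer.io as fsio

    magic = _read_magic(path)
    if magic != _SURF_MAGIC:
        if magic == _CURV_MAGIC:
            raise UnsupportedFormatError(
                f"{path}: curv/morph-data magic where a triangle surface "
                "was expected"
            )
        raise UnsupportedFormatError(
            f"{path}: not a FreeSurfer triangle surface (magic {magic!r})"
        )
    try:
        coords, faces = fsio.read_geometry(str(path))
    except Exception as exc:  # noqa: BLE001 - map onto package error
        import os

        raise FormatParseError(
            f"{path}: truncated or corrupt surface file "
            f"(parse failed; file ends at byte {os.path.getsize(path)})"
        ) from exc
    return Mesh(coords, faces, hemisphere)


def write_surface(mesh: Mesh, path) -> None:
    """Write a mesh in FreeSurfer binary triangle-surface format."""
    import nibabel.freesurfer.io as fsio

    mesh.validate()
    fsio.write_geometry(str(path), mesh.coords, mesh.faces.astype(np.int32))


def read_vertex_field(path, expected_V: int, feature: str = "stat",
                      units: str = "unitless") -> VertexField:
    """Read a per-vertex field from a curv file or one-value-per-line text."""
    import nibabel.freesurfer.io as fsio

    magic = _read_magic(path)
    if magic == _CURV_MAGIC:
        try:
            values = fsio.read_morph_data(str(path))
        except Exception as exc:  # noqa: BLE001
            import os

            raise FormatParseError(
                f"{path}: truncated or corrupt curv file "
                f"(file ends at byte {os.path.getsize(path)})"
            ) from exc
    elif magic == _SURF_MAGIC:
        raise UnsupportedFormatError(
            f"{path}: triangle-surface magic where a vertex field was expected"
        )
    else:
        values = _read_text_field(path)
    if values.size != expected_V:
        raise ShapeError(
            f"{path}: field has {values.size} values, expected {expected_V}"
        )
    return VertexField(values, feature=feature, units=units)


def _read_text_field(path) -> np.ndarray:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                out.append(float(tok))
            except ValueError as exc:
                raise FormatParseError(
                    f"{path}: non-numeric token {tok!r} on line {lineno}"
                ) from exc
    return np.asarray(out)


def write_vertex_field(field: VertexField, path, fmt: str = "curv") -> None:
    """Write a vertex field as a curv file (``fmt='curv'``) or text."""
    import nibabel.freesurfer.io as fsio

    if fmt == "curv":
        fsio.write_morph_data(str(path), field.values)
    elif fmt == "text":
        with open(path, "w") as fh:
            for v in field.values:
                fh.write(f"{float(v)!r}\n")
    else:
        raise ValueError(f"unknown vertex-field format {fmt!r}")


# ---------------------------------------------------------------------------
# adjacency


def build_adjacency(mesh: Mesh) -> sp.csr_matrix:
    """Symmetric, irreflexive vertex adjacency from shared face edges."""
    e = mesh.edges()
    V = mesh.n_vertices
    data = np.ones(len(e))
    A = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(V, V))
    A = A + A.T
    return A.tocsr()


def neighbor_lists(mesh: Mesh) -> list[np.ndarray]:
    A = build_adjacency(mesh)
    return [A.indices[A.indptr[i]:A.indptr[i + 1]] for i in range(mesh.n_vertices)]


# ---------------------------------------------------------------------------
# smoothing


@dataclass
class SurfaceSmoother:
    """Iterated graph-diffusion smoother calibrated to a geodesic FWHM.

    One diffusion step is ``x <- (I - tau * L) x`` with ``L = D - A`` the
    combinatorial graph Laplacian.  The step operator is symmetric and
    row-stochastic, so constants are preserved exactly and total mass is
    conserved.  A step with rate ``tau`` spreads each unit of mass along each
    incident edge with probability ``tau``, adding per-axis positional
    variance ``v(tau) = tau * sum_e |e|^2 / V`` on a 2-D manifold.  The number
    of full steps and the rate of one final partial step are chosen so the
    accumulated variance equals the Gaussian target
    ``sigma^2 = FWHM^2 / (8 ln 2)``.
    """

    mesh: Mesh
    fwhm_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        A = build_adjacency(self.mesh)
        deg = np.asarray(A.sum(axis=1)).ravel()
        V = self.mesh.n_vertices
        L = sp.diags(deg) - A
        lengths = self.mesh.edge_lengths()
        v_unit = float((lengths**2).sum()) / V  # variance per unit tau
        sigma2 = self.fwhm_mm**2 / _LN2_8
        tau_full = 0.5 / float(deg.max())  # keeps all operator entries >= 0
        n_full = int(sigma2 / (tau_full * v_unit))
        tau_last = (sigma2 - n_full * tau_full * v_unit) / v_unit
        self._ops: list[sp.csr_matrix] = []
        I = sp.identity(V, format="csr")
        if n_full:
            self._ops.append((I - tau_full * L).tocsr())
        if tau_last > 1e-15:
            self._ops.append((I - tau_last * L).tocsr())
        self._n_full = n_full
        self._tau_full = tau_full
        self._tau_last = tau_last

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Smooth a (V,) field or an (n, V) matrix of fields."""
        x = np.asarray(values, dtype=np.float64)
        one_d = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.mesh.n_vertices:
            raise ShapeError(
                f"field length {x.shape[1]} != mesh V {self.mesh.n_vertices}"
            )
        if self._ops:
            ops = ([self._ops[0]] * self._n_full + self._ops[1:]
                   if self._n_full else self._ops)
            for op in ops:
                x = x @ op  # op symmetric: right-multiplication == smoothing
        return x[0] if one_d else x


def smooth_field(mesh: Mesh, field: VertexField | np.ndarray,
                 fwhm_mm: float) -> VertexField | np.ndarray:
    """Smooth a per-vertex field with a surface kernel of the given FWHM."""
    smoother = SurfaceSmoother(mesh, fwhm_mm)
    if isinstance(field, VertexField):
        field.validate(mesh)
        return VertexField(smoother.apply(field.values), field.feature,
                           field.units)
    return smoother.apply(field)
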