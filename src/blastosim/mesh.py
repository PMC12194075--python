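"""Closed triangulated cortex meshes.

A simulated cell is a closed, consistently wound triangle mesh whose
vertices are point masses and whose edges are nonlinear springs.  This
module builds the reference geometry (subdivided icosahedra), computes
mesh quantities (signed volume, areas, outward vertex normals) and
assigns the polar "band coordinate" used to address regions of the cell
surface (0% at the apical pole, 100% at the basal pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "CellMesh",
    "RegionSpec",
    "build_icosphere",
    "signed_volume",
    "band_coordinate",
    "select_region",
    "vertex_normals",
    "sphericity",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """A closed 2-manifold triangle mesh with outward-wound faces.

    Attributes
    ----------
    positions : (V, 3) float array
        Vertex coordinates in model length units.
    edges : (E, 2) int array
        Unordered vertex-index pairs, each row sorted ascending.
    faces : (F, 3) int array
        Vertex-index triples with consistent outward winding.
    """

    positions: np.ndarray
    edges: np.ndarray
    faces: np.ndarray

    def validate(self) -> None:
        """Check closed-manifold invariants; raise ``ValueError`` if violated."""
        v, e, f = len(self.positions), len(self.edges), len(self.faces)
        if v - e + f != 2:
            raise ValueError(f"Euler characteristic V-E+F = {v - e + f}, expected 2")
        # every edge must border exactly two faces
        fe = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(fe, axis=0, return_counts=True)
        if len(uniq) != e or not np.all(counts == 2):
            raise ValueError("mesh is not a closed 2-manifold (edge/face incidence)")
        if signed_volume(self, check=False) <= 0:
            raise ValueError("signed volume not positive: winding is not outward")


@dataclass
class CellMesh(TriMesh):
    """A cell cortex: :class:`TriMesh` plus mechanical and regional state.

    Per-edge state: ``l_rest`` (base/reference length), ``l0`` (current
    rest length, i.e. the length the spring tries to reach) and
    stiffness ``k``.  Per-vertex state: the band coordinate in percent
    of polar arc from the apical pole.  ``V0`` is the conserved rest
    volume; ``volume()`` recomputes the current volume from positions.
    """

    l_rest: np.ndarray = field(default=None)  # (E,)
    l0: np.ndarray = field(default=None)  # (E,)
    k: np.ndarray = field(default=None)  # (E,)
    band: np.ndarray = field(default=None)  # (V,) percent in [0, 100]
    apical_axis: np.ndarray = field(default=None)  # (3,) unit vector
    V0: float = 0.0
    cell_id: int = 0
    cell_type: str = "other"

    def volume(self) -> float:
        return signed_volume(self, check=False)

    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def copy(self) -> "CellMesh":
        return CellMesh(
            positions=self.positions.copy(),
            edges=self.edges.copy(),
            faces=self.faces.copy(),
            l_rest=self.l_rest.copy(),
            l0=self.l0.copy(),
            k=self.k.copy(),
            band=self.band.copy(),
            apical_axis=self.apical_axis.copy(),
            V0=self.V0,
            cell_id=self.cell_id,
            cell_type=self.cell_type,
        )


@dataclass(frozen=True)
class RegionSpec:
    """A band on the cell surface, in percent of polar arc from the apical pole."""

    band_start_pct: float
    band_end_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.band_start_pct <= self.band_end_pct <= 100.0):
            raise ValueError(
                f"invalid region band [{self.band_start_pct}, {self.band_end_pct}]"
            )


# ---------------------------------------------------------------------------
# icosphere construction
# ---------------------------------------------------------------------------

# regular icosahedron with circumradius 1 (golden-ratio construction)
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_VERTS /= np.linalg.norm(_ICO_VERTS[0])
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def _edges_from_faces(faces: np.ndarray) -> np.ndarray:
    fe = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    return np.unique(fe, axis=0)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    """One round of edge-midpoint subdivision with exact index-pair merging.

    Shared midpoints are merged by their (sorted) parent-index pair, so
    the result is watertight by construction without any coordinate
    tolerance, and the vertex ordering is deterministic.
    """
    edges = _edges_from_faces(faces)
    mid_index = {tuple(e): len(verts) + i for i, e in enumerate(edges)}
    midpoints = 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])
    new_verts = np.vstack([verts, midpoints])

    def mid(a, b):
        return mid_index[(a, b) if a < b else (b, a)]

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces[4 * i + 0] = (a, ab, ca)
        new_faces[4 * i + 1] = (b, bc, ab)
        new_faces[4 * i + 2] = (c, ca, bc)
        new_faces[4 * i + 3] = (ab, bc, ca)
    return new_verts, new_faces


def build_icosphere(
    subdivision_level: int = 3,
    radius: float = 1.0,
    center=(0.0, 0.0, 0.0),
    apical_axis=(0.0, 0.0, 1.0),
    stiffness: float = 0.5,
    cell_id: int = 0,
    cell_type: str = "other",
) -> CellMesh:
    """Build a subdivided-icosahedron cell mesh.

    A regular icosahedron is subdivided ``subdivision_level`` times by
    edge-midpoint insertion, each new vertex projected back onto the
    sphere of the given radius.  Level 0 gives 12 vertices / 20 faces,
    level 2 gives 162 / 320 and level 3 the 642-vertex / 1280-face mesh
    used for full-size cells.  Rest lengths ``l_rest`` and ``l0`` are
    initialised to the as-built edge lengths, ``V0`` to the signed mesh
    volume, and the band coordinate of every vertex is assigned from
    ``apical_axis`` (0% at the apical pole).
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    center = np.asarray(center, dtype=float)
    apical_axis = np.asarray(apical_axis, dtype=float)
    if not (np.isfinite(radius) and radius > 0):
        raise ValueError(f"radius must be finite and positive, got {radius}")
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")

    verts, faces = _ICO_VERTS.copy(), _ICO_FACES.copy()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)

    positions = center + radius * verts
    edges = _edges_from_faces(faces)
    lengths = np.linalg.norm(positions[edges[:, 1]] - positions[edges[:, 0]], axis=1)
    band = band_coordinate(positions, center, apical_axis)

    cell = CellMesh(
        positions=positions,
        edges=edges,
        faces=faces,
        l_rest=lengths.copy(),
        l0=lengths.copy(),
        k=np.full(len(edges), float(stiffness)),
        band=band,
        apical_axis=apical_axis / np.linalg.norm(apical_axis),
        cell_id=cell_id,
        cell_type=cell_type,
    )
    cell.V0 = cell.volume()
    return cell


# ---------------------------------------------------------------------------
# mesh quantities
# ---------------------------------------------------------------------------


def _face_cross(positions: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-face cross product (v1-v0) x (v2-v0); |.|/2 is the area, direction the normal."""
    p0 = positions[faces[:, 0]]
    return np.cross(positions[faces[:, 1]] - p0, positions[faces[:, 2]] - p0)


def signed_volume(mesh: TriMesh, check: bool = True) -> float:
    """Signed volume of a closed mesh via the divergence theorem.

    Computes (1/3) Σ_faces x_i · n̂_i A_i with x_i a point of face i.
    Positive for outward winding; independent of the coordinate origin
    for a closed surface.
    """
    if check:
        fe = np.sort(
            np.concatenate(
                [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(fe, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("signed_volume requires a closed mesh")
    cross = _face_cross(mesh.positions, mesh.faces)  # n̂_i * 2A_i
    return float(np.einsum("ij,ij->", mesh.positions[mesh.faces[:, 0]], cross) / 6.0)


def surface_area(mesh: TriMesh) -> float:
    cross = _face_cross(mesh.positions, mesh.faces)
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def sphericity(mesh: TriMesh) -> float:
    """π^(1/3) (6V)^(2/3) / A — equals 1 for a perfect sphere."""
    v = signed_volume(mesh, check=False)
    a = surface_area(mesh)
    return float(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / a)


def band_coordinate(positions, center, apical_axis) -> np.ndarray:
    """Polar band coordinate in percent: 100·θ/π.

    θ is the polar angle between (vertex − center) and the apical axis,
    so the apical pole maps to 0, the equator to 50 and the basal pole
    to 100.  Region percentages everywhere in the package refer to this
    fraction of the polar arc (not of axial height or surface area).
    """
    apical_axis = np.asarray(apical_axis, dtype=float)
    norm = np.linalg.norm(apical_axis)
    if norm == 0:
        raise ValueError("apical_axis must be non-zero")
    axis = apical_axis / norm
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    rel = np.atleast_2d(pos - np.asarray(center, dtype=float))
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0):
        raise ValueError("vertex coincides with the cell center")
    cosang = np.clip(rel @ axis / r, -1.0, 1.0)
    out = 100.0 * np.arccos(cosang) / np.pi
    return float(out[0]) if single else out


def select_region(cell: CellMesh, spec: RegionSpec):
    """Vertices and edges inside a band.

    Returns ``(vertex_idx, edge_idx)``: the vertices whose band
    coordinate lies in [start, end] and the edges whose *both* endpoints
    are inside (an edge is never half-inside a region).
    """
    inside = (cell.band >= spec.band_start_pct) & (cell.band <= spec.band_end_pct)
    vertex_idx = np.nonzero(inside)[0]
    edge_idx = np.nonzero(inside[cell.edges[:, 0]] & inside[cell.edges[:, 1]])[0]
    return vertex_idx, edge_idx


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Outward unit vertex normals, area-weighted over adjacent faces.

    Each face's cross product (direction = normal, magnitude = 2×area)
    is accumulated on its three corners and the result normalised; a
    vertex whose accumulated normal degenerates to zero length (only
    possible with zero-area neighbourhoods) falls back to an unweighted
    face-normal average.
    """
    cross = _face_cross(mesh.positions, mesh.faces)
    acc = np.zeros_like(mesh.positions)
    for c in range(3):
        np.add.at(acc, mesh.faces[:, c], cross)
    norms = np.linalg.norm(acc, axis=1)
    bad = norms < 1e-300
    if np.any(bad):
        unit = cross / np.maximum(np.linalg.norm(cross, axis=1, keepdims=True), 1e-300)
        acc2 = np.zeros_like(acc)
        for c in range(3):
            np.add.at(acc2, mesh.faces[:, c], unit)
        acc[bad] = acc2[bad]
        norms = np.linalg.norm(acc, axis=1)
    return acc / norms[:, None]
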