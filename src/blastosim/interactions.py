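"""Intercellular mechanics.

Three couplings act between cells:

* stochastic adhesion bonds — constant-force links between one vertex
  on each of two cells, formed and broken with per-step probabilities
  inside each cell's adhesive band;
* vertex–triangle collision handling — a vertex that penetrates
  another cell's boundary and the violated face both receive
  restoring forces proportional to the penetration depth;
* static confinement planes used by the planar (cross-section)
  experiments.

An axis-aligned bounding box (AABB) per cell prunes the pairwise work:
only cells whose inflated boxes overlap are examined, and only the
vertices/faces inside the overlap region are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CellMesh, RegionSpec, select_region

__all__ = [
    "AdhesionParams",
    "AdhesionBond",
    "CollisionContact",
    "ConfinementPlane",
    "cell_aabbs",
    "broad_phase",
    "update_bonds",
    "adhesion_force",
    "narrow_phase",
    "collision_response",
    "plane_confinement",
    "closest_point_on_triangles",
]


# ---------------------------------------------------------------------------
# parameter / record types
# ---------------------------------------------------------------------------


@dataclass
class AdhesionParams:
    """Adhesion behaviour of one cell type.

    region : adhesive band on the cell surface.
    connect_length : maximum distance at which two vertices may bond.
    k_adh : pull force of a bond (constant beyond ``lin_length``).
    lin_length : below this separation the force ramps linearly to zero,
        which avoids on/off chatter ("bouncing") near contact.
    adhesion_chance, break_chance : percentages (0–100) with which an
        eligible pair bonds / an existing bond is released so the
        vertex may reattach elsewhere.  By default they apply per
        attempt (per detection step); with ``chance_per_time`` they are
        interpreted per time unit and scaled by the elapsed simulation
        time between attempts.
    """

    region: RegionSpec = field(default_factory=lambda: RegionSpec(20.0, 100.0))
    connect_length: float = 0.3
    k_adh: float = 0.5
    lin_length: float = 0.05
    adhesion_chance: float = 100.0
    break_chance: float = 0.0
    chance_per_time: bool = False

    def __post_init__(self) -> None:
        if self.connect_length <= 0:
            raise ValueError("connect_length must be > 0")
        if not (0 < self.lin_length <= self.connect_length):
            raise ValueError("lin_length must be in (0, connect_length]")
        for name in ("adhesion_chance", "break_chance"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class AdhesionBond:
    """A constant-force link between one vertex on each of two cells."""

    cell_a: int
    vertex_a: int
    cell_b: int
    vertex_b: int
    created: float = 0.0


@dataclass(frozen=True)
class CollisionContact:
    """A vertex of one cell detected inside another cell's boundary."""

    intruding_cell: int
    intruding_vertex: int
    violated_cell: int
    violated_face: int
    depth: float  # perpendicular distance vertex-to-face plane, > 0
    barycentric: tuple  # foot point weights on the violated face


@dataclass
class ConfinementPlane:
    """An immovable half-space boundary; vertices crossing it are pushed back."""

    point: np.ndarray
    normal: np.ndarray
    stiffness: float = 20.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / nn


# ---------------------------------------------------------------------------
# broad phase
# ---------------------------------------------------------------------------


def cell_aabbs(cells, margin: float = 0.0) -> np.ndarray:
    """(n, 2, 3) array of per-cell AABB (min, max) corners, inflated by ``margin``."""
    boxes = np.empty((len(cells), 2, 3))
    for i, c in enumerate(cells):
        boxes[i, 0] = c.positions.min(axis=0) - margin
        boxes[i, 1] = c.positions.max(axis=0) + margin
    return boxes


def broad_phase(cells, margin: float = 0.0):
    """Candidate interacting cell pairs by AABB overlap.

    Returns ``(pairs, overlaps)`` where ``pairs`` is a list of index
    pairs (i < j) whose inflated boxes overlap and ``overlaps[n]`` is
    the (2, 3) overlap box for pair n.  With a margin at least as large
    as the adhesion connect length, the candidate set can miss no
    actual contact or bondable pair (boxes contain the cells).
    """
    boxes = cell_aabbs(cells, margin)
    lo = np.maximum(boxes[:, None, 0], boxes[None, :, 0])
    hi = np.minimum(boxes[:, None, 1], boxes[None, :, 1])
    ok = np.all(lo <= hi, axis=2)
    iu, ju = np.triu_indices(len(cells), k=1)
    keep = ok[iu, ju]
    pairs = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    overlaps = [np.stack([lo[i, j], hi[i, j]]) for i, j in pairs]
    return pairs, overlaps


def _in_box(points: np.ndarray, box: np.ndarray, pad: float = 0.0) -> np.ndarray:
    return np.all((points >= box[0] - pad) & (points <= box[1] + pad), axis=1)


# ---------------------------------------------------------------------------
# adhesion
# ---------------------------------------------------------------------------


def update_bonds(
    cell_a: CellMesh,
    cell_b: CellMesh,
    params_a: AdhesionParams,
    params_b: AdhesionParams,
    bonded_a: np.ndarray,
    bonded_b: np.ndarray,
    rng: np.random.Generator,
    overlap_box: np.ndarray | None = None,
    t: float = 0.0,
    adhesive_a: np.ndarray | None = None,
    adhesive_b: np.ndarray | None = None,
    chance_scale: float = 1.0,
):
    """Form new bonds between the adhesive bands of two cells.

    Every unbonded adhesive vertex of cell A is offered its nearest
    unbonded adhesive vertex of cell B within the (smaller of the two)
    connect lengths, and bonds with probability adhesion_chance/100;
    then the remaining B vertices get the same pass against A.  Vertices
    are visited in index order and ties go to the lowest partner index,
    so the outcome is a deterministic function of the RNG stream.  A
    vertex never holds more than one bond.  ``bonded_a``/``bonded_b``
    are per-vertex boolean masks updated in place; the new
    :class:`AdhesionBond` list is returned.
    """
    connect = min(params_a.connect_length, params_b.connect_length)
    chance = min(params_a.adhesion_chance, params_b.adhesion_chance) / 100.0
    chance = min(1.0, chance * chance_scale)
    if chance == 0.0:
        return []
    if adhesive_a is None:
        adhesive_a, _ = select_region(cell_a, params_a.region)
    if adhesive_b is None:
        adhesive_b, _ = select_region(cell_b, params_b.region)
    va, vb = adhesive_a, adhesive_b
    if overlap_box is not None:
        va = va[_in_box(cell_a.positions[va], overlap_box, pad=connect)]
        vb = vb[_in_box(cell_b.positions[vb], overlap_box, pad=connect)]
    va = va[~bonded_a[va]]
    vb = vb[~bonded_b[vb]]
    if len(va) == 0 or len(vb) == 0:
        return []

    pa = cell_a.positions[va]
    pb = cell_b.positions[vb]
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    limit2 = connect * connect
    new = []
    free_b = np.ones(len(vb), dtype=bool)
    for ia in range(len(va)):
        row = np.where(free_b, d2[ia], np.inf)
        ib = int(np.argmin(row))
        if row[ib] > limit2:
            continue
        if chance >= 1.0 or rng.random() < chance:
            new.append(AdhesionBond(cell_a.cell_id, int(va[ia]), cell_b.cell_id, int(vb[ib]), t))
            bonded_a[va[ia]] = True
            bonded_b[vb[ib]] = True
            free_b[ib] = False
    # second pass: remaining free B vertices scan A's still-free vertices
    free_a = ~bonded_a[va]
    if np.any(free_a) and np.any(free_b):
        for jb in np.nonzero(free_b)[0]:
            col = np.where(free_a, d2[:, jb], np.inf)
            ia = int(np.argmin(col))
            if col[ia] > limit2:
                continue
            if chance >= 1.0 or rng.random() < chance:
                new.append(
                    AdhesionBond(cell_a.cell_id, int(va[ia]), cell_b.cell_id, int(vb[jb]), t)
                )
                bonded_a[va[ia]] = True
                bonded_b[vb[jb]] = True
                free_a[ia] = False
    return new


def adhesion_force(separation: np.ndarray, k_adh: float, lin_length: float):
    """Scalar attraction magnitude of a bond at separation l.

    Constant k_adh beyond ``lin_length`` and a linear ramp
    k_adh·l/lin_length below it, so the force is continuous,
    non-decreasing in l, and vanishes at l = 0 (both branches agree at
    l = lin_length).  The direction — toward the partner vertex — is
    applied by the caller; the two endpoints receive equal and opposite
    vectors.
    """
    l = np.asarray(separation, dtype=float)
    return np.where(l > lin_length, k_adh, k_adh * l / lin_length)


# ---------------------------------------------------------------------------
# collision narrow phase
# ---------------------------------------------------------------------------


def closest_point_triangle(points: np.ndarray, a, b, c):
    """Closest point on triangles (a, b, c) to ``points``, broadcast elementwise.

    All inputs have shape (..., 3) with a common leading shape; returns
    ``(closest, bary)`` of shapes (..., 3).  Standard Voronoi-region
    construction.
    """
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = points - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = points - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    shape = d1.shape
    u = np.empty(shape)
    v = np.empty(shape)
    done = np.zeros(shape, dtype=bool)

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    u[reg_a] = 0.0
    v[reg_a] = 0.0
    done |= reg_a
    reg_b = ~done & (d3 >= 0) & (d4 <= d3)
    u[reg_b] = 1.0
    v[reg_b] = 0.0
    done |= reg_b
    reg_c = ~done & (d6 >= 0) & (d5 <= d6)
    u[reg_c] = 0.0
    v[reg_c] = 1.0
    done |= reg_c
    # edge AB
    reg_ab = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
    u[reg_ab] = t_ab[reg_ab]
    v[reg_ab] = 0.0
    done |= reg_ab
    # edge AC
    reg_ac = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = d2 / (d2 - d6)
    u[reg_ac] = 0.0
    v[reg_ac] = t_ac[reg_ac]
    done |= reg_ac
    # edge BC
    reg_bc = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    u[reg_bc] = 1.0 - t_bc[reg_bc]
    v[reg_bc] = t_bc[reg_bc]
    done |= reg_bc
    # interior
    interior = ~done
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        u_in = vb / denom
        v_in = vc / denom
    u[interior] = u_in[interior]
    v[interior] = v_in[interior]

    closest = a + u[..., None] * ab + v[..., None] * ac
    bary = np.stack([1.0 - u - v, u, v], axis=-1)
    return closest, bary


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray):
    """All-pairs closest points: ``points`` (n, 3) against ``tri`` (m, 3, 3).

    Returns ``(closest, bary)`` of shapes (n, m, 3).
    """
    p = points[:, None, :]
    return closest_point_triangle(
        p, tri[None, :, 0], tri[None, :, 1], tri[None, :, 2]
    )


def _one_direction_contacts(
    intruder: CellMesh, target: CellMesh, overlap_box: np.ndarray, pad: float
):
    """Contacts of ``intruder`` vertices inside ``target``'s boundary.

    A vertex is inside when the signed distance to its nearest surface
    feature is negative, i.e. it lies behind the outward normal of the
    nearest face.  Only vertices and faces near the AABB overlap region
    are examined; for vertices no deeper than the overlap region this
    loses no contacts.
    """
    vmask = _in_box(intruder.positions, overlap_box, pad)
    vidx = np.nonzero(vmask)[0]
    if len(vidx) == 0:
        return []
    fverts_in = _in_box(target.positions, overlap_box, pad)
    fmask = fverts_in[target.faces].any(axis=1)
    fidx = np.nonzero(fmask)[0]
    if len(fidx) == 0:
        return []
    tri = target.positions[target.faces[fidx]]  # (m, 3, 3)
    pts = intruder.positions[vidx]
    closest, bary = closest_point_on_triangles(pts, tri)
    dist2 = ((pts[:, None, :] - closest) ** 2).sum(axis=2)
    nearest = np.argmin(dist2, axis=1)

    crosses = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas2 = np.linalg.norm(crosses, axis=1)
    contacts = []
    for i, j in enumerate(nearest):
        if areas2[j] < 1e-300:
            continue  # degenerate face
        normal = crosses[j] / areas2[j]
        signed = float(np.dot(pts[i] - tri[j, 0], normal))
        if signed >= 0:
            continue
        contacts.append(
            CollisionContact(
                intruding_cell=intruder.cell_id,
                intruding_vertex=int(vidx[i]),
                violated_cell=target.cell_id,
                violated_face=int(fidx[j]),
                depth=-signed,
                barycentric=tuple(float(w) for w in bary[i, j]),
            )
        )
    return contacts


def narrow_phase(
    cell_a: CellMesh, cell_b: CellMesh, overlap_box: np.ndarray, pad: float = 0.05
):
    """All vertex-through-face contacts between a candidate cell pair.

    Tests A's vertices against B's faces and vice versa, restricted to
    the AABB overlap region (padded by ``pad``).  Each contact reports
    the nearest violated face, the perpendicular penetration depth and
    the barycentric foot point.
    """
    return _one_direction_contacts(cell_a, cell_b, overlap_box, pad) + (
        _one_direction_contacts(cell_b, cell_a, overlap_box, pad)
    )


def collision_response(contact: CollisionContact, intruder: CellMesh, target: CellMesh, k_col: float):
    """Restoring forces for one contact.

    The intruding vertex is pushed out along the violated face's
    outward normal with magnitude k_col × depth; the three face corners
    share the opposite force, weighted by the foot point's barycentric
    coordinates, so the four force vectors sum to zero.

    Returns ``(force_on_vertex, corner_forces (3, 3))`` or ``None`` for
    a degenerate face.
    """
    face = target.faces[contact.violated_face]
    tri = target.positions[face]
    cr = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    norm = np.linalg.norm(cr)
    if norm < 1e-300:
        return None
    normal = cr / norm
    f = k_col * contact.depth * normal
    w = np.asarray(contact.barycentric)
    corner_forces = -w[:, None] * f[None, :]
    return f, corner_forces


# ---------------------------------------------------------------------------
# confinement planes
# ---------------------------------------------------------------------------


def plane_confinement(positions: np.ndarray, plane: ConfinementPlane) -> np.ndarray:
    """Per-vertex restoring forces from one immovable plane.

    Vertices on the negative side of the plane (against the normal) get
    a force stiffness × depth along the normal; all others get zero.
    """
    depth = -(positions - plane.point) @ plane.normal
    depth = np.maximum(depth, 0.0)
    return plane.stiffness * depth[:, None] * plane.normal[None, :]
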