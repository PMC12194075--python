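"""Adhesion bonds, collision detection/response, planes, broad phase."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blastosim as bs
from blastosim.interactions import (
    AdhesionParams,
    ConfinementPlane,
    adhesion_force,
    broad_phase,
    closest_point_on_triangles,
    collision_response,
    narrow_phase,
    plane_confinement,
    update_bonds,
)
from blastosim.mesh import RegionSpec, build_icosphere


def brute_force_contacts(cell_a, cell_b):
    """Exhaustive all-vertex / all-face inside test (independent oracle)."""
    out = []
    for intr, targ in ((cell_a, cell_b), (cell_b, cell_a)):
        tri = targ.positions[targ.faces]
        closest, _ = closest_point_on_triangles(intr.positions, tri)
        d2 = ((intr.positions[:, None, :] - closest) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        crosses = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals = crosses / np.linalg.norm(crosses, axis=1, keepdims=True)
        for i, j in enumerate(nearest):
            signed = np.dot(intr.positions[i] - tri[j, 0], normals[j])
            if signed < 0:
                out.append((intr.cell_id, i, targ.cell_id))
    return sorted(out)


# ---------------------------------------------------------------------------
# broad phase
# ---------------------------------------------------------------------------


class TestBroadPhase:
    def test_far_apart_cells_no_candidates(self):
        a = build_icosphere(1, center=(0, 0, 0), cell_id=0)
        b = build_icosphere(1, center=(10, 0, 0), cell_id=1)
        pairs, _ = broad_phase([a, b], margin=0.5)
        assert pairs == []

    def test_overlapping_cells_are_candidates(self):
        a = build_icosphere(1, center=(0, 0, 0), cell_id=0)
        b = build_icosphere(1, center=(1.5, 0, 0), cell_id=1)
        pairs, boxes = broad_phase([a, b], margin=0.0)
        assert pairs == [(0, 1)]
        assert np.all(boxes[0][0] <= boxes[0][1])

    def test_completeness_against_bruteforce(self):
        """Broad+narrow contacts equal the exhaustive all-pairs scan.

        Randomized 8-cell scenes: the AABB prefilter must lose no
        contact found by brute force, across many seeds.
        """
        for seed in range(50):
            rng = np.random.default_rng(seed)
            centers = rng.uniform(0, 5.0, size=(8, 3))
            cells = [
                build_icosphere(1, center=c, cell_id=i)
                for i, c in enumerate(centers)
            ]
            # brute force over all pairs
            expected = []
            for i in range(8):
                for j in range(i + 1, 8):
                    expected.extend(brute_force_contacts(cells[i], cells[j]))
            # pipeline
            pairs, boxes = broad_phase(cells, margin=0.0)
            got = []
            for (i, j), box in zip(pairs, boxes):
                for ct in narrow_phase(cells[i], cells[j], box, pad=2.1):
                    got.append((ct.intruding_cell, ct.intruding_vertex, ct.violated_cell))
            assert sorted(got) == sorted(expected), f"seed {seed}"


# ---------------------------------------------------------------------------
# adhesion
# ---------------------------------------------------------------------------


def _touching_pair():
    a = build_icosphere(1, center=(0, 0, 0), cell_id=0)
    b = build_icosphere(1, center=(2.1, 0, 0), cell_id=1)
    return a, b


class TestAdhesion:
    def test_force_law(self):
        # zero at contact, continuous at lin_length, constant beyond
        assert adhesion_force(0.0, k_adh=0.4, lin_length=0.1) == pytest.approx(0.0)
        assert adhesion_force(0.1, 0.4, 0.1) == pytest.approx(0.4)
        assert adhesion_force(0.2, 0.4, 0.1) == pytest.approx(0.4)
        assert adhesion_force(0.05, 0.4, 0.1) == pytest.approx(0.2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(l=st.floats(0.0, 2.0), dl=st.floats(1e-9, 0.5))
    def test_force_monotone_and_continuous(self, l, dl):
        f1 = adhesion_force(l, 0.3, 0.07)
        f2 = adhesion_force(l + dl, 0.3, 0.07)
        assert f2 >= f1 - 1e-12
        assert f2 - f1 <= 0.3 / 0.07 * dl + 1e-12  # Lipschitz by the ramp slope

    def test_zero_chance_no_bonds(self):
        a, b = _touching_pair()
        params = AdhesionParams(region=RegionSpec(0, 100), adhesion_chance=0.0)
        bonds = update_bonds(a, b, params, params,
                             np.zeros(42, bool), np.zeros(42, bool),
                             np.random.default_rng(0))
        assert bonds == []

    def test_full_chance_bonds_nearest_pair(self):
        a, b = _touching_pair()
        params = AdhesionParams(region=RegionSpec(0, 100), connect_length=0.3,
                                adhesion_chance=100.0)
        ba, bb = np.zeros(42, bool), np.zeros(42, bool)
        bonds = update_bonds(a, b, params, params, ba, bb, np.random.default_rng(0))
        assert len(bonds) >= 1
        for bond in bonds:
            d = np.linalg.norm(b.positions[bond.vertex_b] - a.positions[bond.vertex_a])
            assert d <= params.connect_length

    def test_determinism_under_fixed_seed(self):
        a, b = _touching_pair()
        params = AdhesionParams(region=RegionSpec(0, 100), adhesion_chance=40.0)
        out = []
        for _ in range(2):
            ba, bb = np.zeros(42, bool), np.zeros(42, bool)
            bonds = update_bonds(a, b, params, params, ba, bb,
                                 np.random.default_rng(123))
            out.append([(x.vertex_a, x.vertex_b) for x in bonds])
        assert out[0] == out[1]

    def test_bond_exclusivity(self):
        """No vertex ever holds two bonds at once."""
        a, b = _touching_pair()
        params = AdhesionParams(region=RegionSpec(0, 100), connect_length=0.5)
        ba, bb = np.zeros(42, bool), np.zeros(42, bool)
        bonds = update_bonds(a, b, params, params, ba, bb, np.random.default_rng(1))
        seen_a = [x.vertex_a for x in bonds]
        seen_b = [x.vertex_b for x in bonds]
        assert len(seen_a) == len(set(seen_a))
        assert len(seen_b) == len(set(seen_b))
        # a second pass adds nothing new for already-bonded vertices
        again = update_bonds(a, b, params, params, ba, bb, np.random.default_rng(2))
        assert not (set(x.vertex_a for x in again) & set(seen_a))

    def test_bond_count_nondecreasing_until_saturation(self):
        """Touching cells at 100% adhesion / 0% break only gain bonds."""
        scene = bs.Scene(
            [build_icosphere(1, center=(0, 0, 0), cell_id=0),
             build_icosphere(1, center=(2.05, 0, 0), cell_id=1)],
            adhesion={"other": AdhesionParams(region=RegionSpec(0, 100),
                                              adhesion_chance=100.0,
                                              break_chance=0.0)},
            seed=3,
        )
        counts = []
        for _ in range(60):
            scene.step()
            counts.append(scene.bond_count())
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))
        assert counts[-1] > 0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AdhesionParams(connect_length=0.0)
        with pytest.raises(ValueError):
            AdhesionParams(lin_length=0.5, connect_length=0.3)
        with pytest.raises(ValueError):
            AdhesionParams(adhesion_chance=120.0)


# ---------------------------------------------------------------------------
# collision
# ---------------------------------------------------------------------------


def _tetra(cell_id=0):
    """A regular-ish tetrahedron cell for constructed-geometry tests."""
    from blastosim.mesh import CellMesh

    v = np.array([
        [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
    ])
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    edges = np.unique(np.sort(np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1), axis=0)
    lens = np.linalg.norm(v[edges[:, 1]] - v[edges[:, 0]], axis=1)
    return CellMesh(positions=v, edges=edges, faces=faces,
                    l_rest=lens, l0=lens.copy(), k=np.full(len(edges), 0.5),
                    band=np.zeros(4), apical_axis=np.array([0.0, 0, 1]),
                    V0=1.0, cell_id=cell_id)


class TestCollision:
    def test_separated_cells_no_contacts(self):
        a = build_icosphere(1, center=(0, 0, 0), cell_id=0)
        b = build_icosphere(1, center=(5, 0, 0), cell_id=1)
        box = np.array([[-10.0, -10, -10], [10.0, 10, 10]])
        assert narrow_phase(a, b, box, pad=1.0) == []

    def test_constructed_penetration_depth(self):
        """A probe vertex pushed depth d through a tetra face reports d."""
        target = _tetra(cell_id=1)
        probe = _tetra(cell_id=0)
        # face [1, 3, 2] of the tetra lies in the plane x + y + z = -1
        # with outward normal -(1,1,1)/sqrt(3); push a probe vertex just
        # inside through its centroid
        n = -np.array([1.0, 1, 1]) / np.sqrt(3)
        centroid = target.positions[[1, 3, 2]].mean(axis=0)
        d = 0.05
        probe.positions = probe.positions + (
            centroid - d * n - probe.positions[0]
        )  # vertex 0 sits depth d inside
        box = np.array([[-3.0, -3, -3], [3.0, 3, 3]])
        contacts = [
            c for c in narrow_phase(probe, target, box, pad=3.0)
            if c.intruding_cell == 0
        ]
        assert len(contacts) >= 1
        c0 = min(contacts, key=lambda c: abs(c.depth - d))
        assert c0.depth == pytest.approx(d, abs=1e-9)
        assert c0.intruding_vertex == 0

    def test_response_forces_balance(self):
        target = _tetra(cell_id=1)
        probe = _tetra(cell_id=0)
        n = -np.array([1.0, 1, 1]) / np.sqrt(3)
        centroid = target.positions[[1, 3, 2]].mean(axis=0)
        probe.positions = probe.positions + (centroid - 0.05 * n - probe.positions[0])
        box = np.array([[-3.0, -3, -3], [3.0, 3, 3]])
        contacts = narrow_phase(probe, target, box, pad=3.0)
        for ct in contacts:
            intr = probe if ct.intruding_cell == 0 else target
            targ = target if ct.intruding_cell == 0 else probe
            fv, fc = collision_response(ct, intr, targ, k_col=2.0)
            total = fv + fc.sum(axis=0)
            assert np.allclose(total, 0.0, atol=1e-12)

    def test_centroid_foot_point_splits_evenly(self):
        """Foot point at the face centroid puts 1/3 of the reaction per corner."""
        target = _tetra(cell_id=1)
        probe = _tetra(cell_id=0)
        n = -np.array([1.0, 1, 1]) / np.sqrt(3)
        centroid = target.positions[[1, 3, 2]].mean(axis=0)
        probe.positions = probe.positions + (centroid - 0.02 * n - probe.positions[0])
        box = np.array([[-3.0, -3, -3], [3.0, 3, 3]])
        ct = [c for c in narrow_phase(probe, target, box, pad=3.0)
              if c.intruding_vertex == 0 and c.intruding_cell == 0][0]
        assert np.allclose(ct.barycentric, [1 / 3] * 3, atol=1e-9)
        fv, fc = collision_response(ct, probe, target, k_col=1.0)
        assert np.allclose(fc[0], fc[1]) and np.allclose(fc[1], fc[2])

    def test_forces_vanish_continuously_with_depth(self):
        target = _tetra(cell_id=1)
        probe = _tetra(cell_id=0)
        n = -np.array([1.0, 1, 1]) / np.sqrt(3)
        centroid = target.positions[[1, 3, 2]].mean(axis=0)
        box = np.array([[-3.0, -3, -3], [3.0, 3, 3]])
        mags = []
        for d in (0.1, 0.01, 0.001):
            p = _tetra(cell_id=0)
            p.positions = p.positions + (centroid - d * n - p.positions[0])
            ct = [c for c in narrow_phase(p, target, box, pad=3.0)
                  if c.intruding_vertex == 0 and c.intruding_cell == 0][0]
            fv, _ = collision_response(ct, p, target, k_col=3.0)
            mags.append(np.linalg.norm(fv))
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] == pytest.approx(3.0 * 0.001, rel=1e-6)


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------


class TestPlaneConfinement:
    def test_allowed_side_is_force_free(self):
        plane = ConfinementPlane(point=(0, 0, 0), normal=(0, 0, 1), stiffness=7.0)
        pts = np.array([[0.0, 0, 0.5], [1.0, 2, 0.01]])
        assert np.allclose(plane_confinement(pts, plane), 0.0)

    def test_penetration_force_magnitude(self):
        plane = ConfinementPlane(point=(0, 0, 0), normal=(0, 0, 1), stiffness=7.0)
        pts = np.array([[0.0, 0, -0.2]])
        f = plane_confinement(pts, plane)
        assert np.allclose(f, [[0, 0, 7.0 * 0.2]])

    def test_squeezed_cell_keeps_volume(self):
        """A cell between plates closer than its diameter flattens but
        keeps |ΔV|/V0 ≤ 1% at equilibrium."""
        cell = build_icosphere(2)
        gap = 1.6
        planes = [
            ConfinementPlane((0, 0, -gap / 2), (0, 0, 1), stiffness=20.0),
            ConfinementPlane((0, 0, gap / 2), (0, 0, -1), stiffness=20.0),
        ]
        scene = bs.Scene([cell], planes=planes, seed=0)
        scene.run(80.0)
        assert abs(scene.volumes()[0] / scene.V0[0] - 1.0) <= 0.01
        # flattened: extent along z clamped near the gap
        z_ext = scene.X[:, 2].max() - scene.X[:, 2].min()
        assert z_ext < 2.0 * 0.95
        assert z_ext == pytest.approx(gap, abs=0.25)

    def test_normal_normalized_and_validated(self):
        p = ConfinementPlane((0, 0, 0), (0, 0, 2.0), 1.0)
        assert np.linalg.norm(p.normal) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ConfinementPlane((0, 0, 0), (0, 0, 0), 1.0)


def test_interaction_forces_sum_to_zero_in_scene():
    """Adhesion + collision contributions cancel over the whole scene."""
    cells = [
        build_icosphere(1, center=(0, 0, 0), cell_id=0),
        build_icosphere(1, center=(1.9, 0, 0), cell_id=1),
        build_icosphere(1, center=(0.95, 1.7, 0), cell_id=2),
    ]
    scene = bs.Scene(
        cells,
        adhesion={"other": AdhesionParams(region=RegionSpec(0, 100))},
        seed=5,
    )
    for _ in range(30):
        scene.step()
    scene.accumulate_forces()
    for name in ("adhesion", "collision"):
        if name in scene.last_forces:
            net = scene.last_forces[name].sum(axis=0)
            assert np.allclose(net, 0.0, atol=1e-10)
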