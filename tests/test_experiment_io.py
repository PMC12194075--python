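"""Scripts, metrics, snapshots, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import blastosim as bs
from blastosim import measure, scenes, snapshot
from blastosim.cli import main as cli_main
from blastosim.measure import (
    MeasurementRecorder,
    apical_extents,
    cell_elongation,
    invagination_depth,
    opening_diameter,
    rim_diameter,
)
from blastosim.mesh import RegionSpec, build_icosphere
from blastosim.script import ScriptError, parse_script


# ---------------------------------------------------------------------------
# script parsing
# ---------------------------------------------------------------------------


class TestParseScript:
    def test_minimal_single_cell(self):
        s = parse_script("scene: {builder: single_cell}\nend_time: 5\n")
        scene = s.build()
        assert len(scene.cells) == 1
        scene.run(1.0)  # runs fine with no events

    def test_blastula_simultaneous_constriction(self):
        """A blastula script with a mode event expands to one event per
        ring, all sharing the start time."""
        s = parse_script("""
scene:
  builder: blastula
  n_cells: 32
  plate: {kind: cap, size: 0.9}
params:
  seed: 4
events:
  - type: constrict
    mode: simultaneous
    f_c: 0.1
    start: 50
end_time: 60
""")
        scene = s.build()
        n_rings = len(scene.meta["rings"])
        cons = [e for e in scene.events if isinstance(e, bs.ConstrictionEvent)]
        assert len(cons) == n_rings
        assert all(e.start == 50.0 for e in cons)
        assert all(e.f_c == 0.1 for e in cons)
        plate = set(scene.meta["plate_cells"])
        assert set().union(*(e.cells for e in cons)) == plate

    def test_misspelled_mode_is_named(self):
        with pytest.raises(ScriptError, match="mode"):
            parse_script(
                "scene: {builder: detached_plate}\n"
                "events:\n  - {type: constrict, mode: sidewys}\n"
            )

    def test_unknown_key_is_named(self):
        with pytest.raises(ScriptError, match="wibble"):
            parse_script("scene: {builder: single_cell, wibble: 3}\n")

    def test_unknown_builder_is_named(self):
        with pytest.raises(ScriptError, match="lattice"):
            parse_script("scene: {builder: lattice}\n")

    def test_negative_event_time_rejected(self):
        with pytest.raises(ScriptError, match="t = 0"):
            parse_script(
                "scene: {builder: single_cell}\n"
                "events:\n  - {type: constrict, cells: [0], start: -5}\n"
            )

    def test_defaults_resolved(self):
        s = parse_script("scene: {builder: single_cell}\n")
        assert s.params["dt"] == 0.05
        assert s.params["k_v"] == 50.0
        cfg = s.to_config()
        assert cfg["params"]["f_et"] == 0.5


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestMetrics:
    def test_sphere_elongation_is_one(self, ico2):
        assert cell_elongation(ico2) == pytest.approx(1.0, abs=0.02)

    def test_axially_stretched_cell(self, ico2):
        c = ico2.copy()
        c.positions = c.positions * np.array([1.0, 1.0, 2.0])  # axis is +z
        assert cell_elongation(c) == pytest.approx(2.0, abs=0.05)

    def test_apical_extents_isotropic_on_sphere(self, ico2):
        v, h = apical_extents(ico2, vertical=(1, 0, 0), horizontal=(0, 1, 0))
        assert v == pytest.approx(h, rel=0.02)

    def test_apical_extents_empty_band_rejected(self, ico2):
        with pytest.raises(ValueError):
            # no vertex band coordinate falls strictly inside (0, 8.8)
            apical_extents(ico2, (1, 0, 0), (0, 1, 0), band=RegionSpec(2.0, 5.0))

    def test_rim_diameter_hemispherical_cup(self):
        """A hemispherical cup of radius R with its rim on the equator
        reads 2R within 5%."""
        rng = np.random.default_rng(0)
        n = 4000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        R = 3.0
        shell = R * pts[pts[:, 2] <= 0]  # lower hemisphere, opening up
        d = rim_diameter(shell, axis=(0, 0, 1), centroid=np.zeros(3))
        assert d == pytest.approx(2 * R, rel=0.05)

    def test_rim_diameter_closed_sphere_is_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        assert rim_diameter(3.0 * pts, axis=(0, 0, 1)) == 0.0

    def test_opening_zero_before_constriction(self):
        spec = scenes.BlastulaSpec(n_cells=32, plate=scenes.PlateShape("cap", 0.9))
        sc = scenes.build_blastula(spec, seed=2)
        assert opening_diameter(sc) == 0.0

    def test_invagination_depth_zero_at_start_and_frame_invariant(self):
        sc = scenes.build_detached_plate(19, seed=0)
        assert invagination_depth(sc) == pytest.approx(0.0)
        # rigid translation of the whole scene does not register
        sc.X += np.array([5.0, -2.0, 11.0])
        assert invagination_depth(sc) == pytest.approx(0.0, abs=1e-9)

    def test_metrics_rotation_invariant(self, ico2):
        """Cell metrics ride along with a rigid rotation of the cell."""
        from scipy.spatial.transform import Rotation

        c = ico2.copy()
        c.positions = c.positions * np.array([1.0, 1.0, 1.7])
        base = cell_elongation(c)
        rot = Rotation.from_euler("xyz", [30, -60, 45], degrees=True).as_matrix()
        r = c.copy()
        r.positions = c.positions @ rot.T
        r.apical_axis = rot @ c.apical_axis
        assert cell_elongation(r) == pytest.approx(base, rel=1e-9)

    def test_recorder_stream_monotone_time(self):
        sc = scenes.build_single_cell(seed=0)
        rec = MeasurementRecorder()
        sc.run(3.0, recorder=rec, record_every=10)
        df = rec.frame()
        assert df["t"].is_monotonic_increasing
        assert {"bonds", "kinetic", "volume_0", "elongation_0"} <= set(df.columns)


# ---------------------------------------------------------------------------
# snapshots and restart
# ---------------------------------------------------------------------------


class TestSnapshots:
    def test_obj_round_trip(self, tmp_path):
        sc = scenes.build_detached_plate(7, seed=0)
        path = tmp_path / "snap.obj"
        snapshot.write_obj(sc, path)
        groups = snapshot.read_obj(path)
        assert len(groups) == 7
        for (name, verts, faces), cell in zip(groups, sc.cells):
            assert name == f"cell_{cell.cell_id}"
            assert verts.shape == cell.positions.shape
            assert np.array_equal(faces, cell.faces)

    def test_vtk_contains_scalars(self, tmp_path):
        sc = scenes.build_planar_scene(n_cells=4, n_endoderm=1, seed=0)
        path = tmp_path / "snap.vtk"
        snapshot.write_vtk(sc, path)
        text = path.read_text()
        assert "POINTS 648 float" in text  # 4 x 162 vertices
        for field in ("cell_id", "cell_type", "band"):
            assert f"SCALARS {field}" in text

    def test_restart_matches_uninterrupted_run(self, tmp_path):
        """Snapshot at step N and continue: identical to the run that
        never stopped."""
        def fresh():
            sc = scenes.build_detached_plate(7, seed=5)
            sc.events.extend(scenes.constriction_schedule(
                sc.meta["rings"], scenes.ConstrictionMode("simultaneous"),
                0.1, start=1.0, ramp=2.0))
            return sc

        full = fresh()
        for _ in range(80):
            full.step()

        half = fresh()
        for _ in range(40):
            half.step()
        state = tmp_path / "state.json"
        snapshot.save_state(half, state)
        resumed = snapshot.load_state(state)
        for _ in range(40):
            resumed.step()
        assert np.allclose(resumed.X, full.X, atol=1e-12)
        assert resumed.bond_count() == full.bond_count()

    def test_bond_csv_columns(self, tmp_path):
        import pandas as pd

        sc = scenes.build_detached_plate(7, seed=0)
        for _ in range(20):
            sc.step()
        path = tmp_path / "bonds.csv"
        snapshot.write_bonds_csv(sc, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["step", "cell_a", "vertex_a", "cell_b",
                                    "vertex_b", "length"]
        assert len(df) == sc.bond_count()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


MINI_SCRIPT = """
scene: {builder: single_cell}
params: {seed: 9}
events:
  - {type: constrict, cells: [0], region: [0, 50], f_c: 0.2, start: 0.5, ramp: 1}
end_time: 3
output: {record_every: 10, snapshot_every: 20}
"""


class TestCli:
    def test_validate_ok(self, tmp_path):
        p = tmp_path / "exp.yaml"
        p.write_text(MINI_SCRIPT)
        res = CliRunner().invoke(cli_main, ["validate", str(p)])
        assert res.exit_code == 0
        assert "ok" in res.output

    def test_validate_parse_error_exit_code(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("scene: {builder: nope}\n")
        res = CliRunner().invoke(cli_main, ["validate", str(p)])
        assert res.exit_code == 2

    def test_run_produces_outputs(self, tmp_path):
        p = tmp_path / "exp.yaml"
        p.write_text(MINI_SCRIPT)
        out = tmp_path / "out"
        res = CliRunner().invoke(cli_main, ["run", str(p), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "measurements.csv").exists()
        assert (out / "manifest.json").exists()
        assert (out / "state_final.json").exists()
        # 60 steps, snapshots every 20 -> steps 20, 40, 60
        objs = sorted(out.glob("snapshot_*.obj"))
        assert len(objs) == 3
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 9
        assert manifest["config"]["params"]["seed"] == 9
        assert len(manifest["events"]) == 1

    def test_run_seed_override_reproducible(self, tmp_path):
        p = tmp_path / "exp.yaml"
        p.write_text(MINI_SCRIPT)
        frames = []
        for d in ("a", "b"):
            out = tmp_path / d
            res = CliRunner().invoke(
                cli_main, ["run", str(p), "--out", str(out), "--seed", "77"]
            )
            assert res.exit_code == 0
            frames.append((out / "measurements.csv").read_text())
        assert frames[0] == frames[1]

    def test_measure_offline(self, tmp_path):
        p = tmp_path / "exp.yaml"
        p.write_text(MINI_SCRIPT)
        out = tmp_path / "out"
        CliRunner().invoke(cli_main, ["run", str(p), "--out", str(out)])
        csv = tmp_path / "metrics.csv"
        res = CliRunner().invoke(
            cli_main, ["measure", str(out), "--out", str(csv)]
        )
        assert res.exit_code == 0
        import pandas as pd

        df = pd.read_csv(csv)
        assert len(df) >= 3
        assert df["t"].is_monotonic_increasing


class TestRoundTrips:
    def test_manifest_config_reproduces_the_run(self, tmp_path):
        """Script -> manifest -> script: rebuilding the experiment from
        the manifest's config echo reproduces the identical run."""
        import yaml

        p = tmp_path / "exp.yaml"
        p.write_text(MINI_SCRIPT)
        out1 = tmp_path / "one"
        res = CliRunner().invoke(cli_main, ["run", str(p), "--out", str(out1)])
        assert res.exit_code == 0
        manifest = json.loads((out1 / "manifest.json").read_text())
        p2 = tmp_path / "rebuilt.yaml"
        p2.write_text(yaml.safe_dump(manifest["config"]))
        out2 = tmp_path / "two"
        res = CliRunner().invoke(cli_main, ["run", str(p2), "--out", str(out2)])
        assert res.exit_code == 0
        assert (out1 / "measurements.csv").read_text() == (
            out2 / "measurements.csv"
        ).read_text()

    def test_adhesion_event_switches_parameters_mid_run(self):
        """Two near cells with adhesion disabled bond only after an
        adhesion event enables it."""
        from blastosim.mechanics import AdhesionEvent
        from blastosim.interactions import AdhesionParams
        from blastosim.mesh import RegionSpec, build_icosphere

        off = AdhesionParams(region=RegionSpec(0, 100), adhesion_chance=0.0)
        on = AdhesionParams(region=RegionSpec(0, 100), adhesion_chance=100.0)
        cells = [
            build_icosphere(1, center=(0, 0, 0), cell_id=0),
            build_icosphere(1, center=(2.05, 0, 0), cell_id=1),
        ]
        scene = bs.Scene(
            cells,
            adhesion={"other": off},
            events=[AdhesionEvent(cells=(0, 1), start=1.0, params=on)],
            seed=0,
        )
        scene.run(0.9)
        assert scene.bond_count() == 0
        scene.run(2.0)
        assert scene.bond_count() > 0
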