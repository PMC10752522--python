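"""Retention counting semantics and lossless file round trips."""

import numpy as np
import pytest

from splenosim.analysis_io import (
    RetentionCriterion,
    RetentionTimeSeries,
    count_retained,
    mean_suspension_velocity,
    read_csv_series,
    read_off,
    read_vtk_polydata,
    validate_summary,
    write_csv_series,
    write_off,
    write_outputs,
    write_vtk_polydata,
)


def _toy_trajectory():
    """Three cells over 2 s: one permanently bonded and stationary, one
    transiently bonded (0.3 s), one always free and fast."""
    times = np.linspace(0.0, 2.0, 21)
    bonds = np.zeros((21, 3), dtype=int)
    bonds[:, 0] = 2  # cell 0: bonded throughout
    bonds[(times >= 0.5) & (times < 0.8), 1] = 1  # cell 1: brief
    speeds = np.zeros((21, 3))
    speeds[:, 0] = 1.0
    speeds[:, 1] = 5.0
    speeds[:, 2] = 140.0
    return {"times": times, "bond_counts": bonds, "cell_speeds": speeds}


class TestCountRetained:
    def test_toy_timeline_duration_threshold(self):
        """With a duration threshold between the two bond lifetimes only the
        permanently bonded slow cell counts."""
        traj = _toy_trajectory()
        crit = RetentionCriterion(min_bond_count=1, min_bound_duration=0.5,
                                  max_centroid_speed=15.0)
        series = count_retained(traj, crit)
        assert series.retained_count[-1] == 1
        assert series.retained_count.max() == 1

    def test_transient_cell_counts_with_short_threshold(self):
        traj = _toy_trajectory()
        crit = RetentionCriterion(min_bound_duration=0.1, max_centroid_speed=15.0)
        series = count_retained(traj, crit)
        # during the transient window both bonded cells count
        k = np.flatnonzero((traj["times"] >= 0.7) & (traj["times"] < 0.8))[0]
        assert series.retained_count[k] == 2

    def test_degenerate_criterion_counts_everything(self):
        traj = _toy_trajectory()
        crit = RetentionCriterion(min_bond_count=0, min_bound_duration=0.0,
                                  max_centroid_speed=1e9)
        series = count_retained(traj, crit)
        assert np.all(series.retained_count == 3)

    def test_missing_bond_channel_rejected(self):
        with pytest.raises(ValueError):
            count_retained({"times": np.arange(3.0), "bond_counts": [],
                            "cell_speeds": np.zeros((3, 1))},
                           RetentionCriterion())

    def test_counting_is_pure(self):
        traj = _toy_trajectory()
        crit = RetentionCriterion(min_bound_duration=0.5)
        a = count_retained(traj, crit)
        b = count_retained(traj, crit)
        assert np.array_equal(a.retained_count, b.retained_count)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            RetentionTimeSeries(np.arange(2.0), np.array([-1, 0]), np.zeros(2))


class TestMeanSuspensionVelocity:
    def test_manual_average(self):
        traj = _toy_trajectory()
        t, v = mean_suspension_velocity(traj)
        assert v[0] == pytest.approx((1.0 + 5.0 + 140.0) / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_suspension_velocity({"times": np.zeros(0), "cell_speeds": np.zeros((0, 0))})


class TestCsvRoundTrip:
    def test_byte_identical_round_trip(self, tmp_path):
        series = RetentionTimeSeries(
            np.array([0.0, 0.123456789012345, 1.0]),
            np.array([0, 2, 3]),
            np.array([150.0, 37.70000000001, 0.1]),
        )
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_csv_series(str(p1), series)
        back = read_csv_series(str(p1))
        write_csv_series(str(p2), back)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.time, series.time)
        assert np.array_equal(back.mean_suspension_velocity,
                              series.mean_suspension_velocity)

    def test_collision_without_overwrite(self, tmp_path):
        series = RetentionTimeSeries(np.zeros(1), np.zeros(1, int), np.zeros(1))
        p = tmp_path / "x.csv"
        write_csv_series(str(p), series)
        with pytest.raises(FileExistsError):
            write_csv_series(str(p), series)


class TestMeshFormats:
    def test_vtk_polydata_round_trip(self, tmp_path, biconcave_mesh_small):
        p = tmp_path / "cell.vtk"
        write_vtk_polydata(str(p), biconcave_mesh_small.vertices,
                           list(biconcave_mesh_small.triangles))
        verts, polys = read_vtk_polydata(str(p))
        assert np.array_equal(verts, biconcave_mesh_small.vertices)
        assert np.array_equal(np.asarray(polys), biconcave_mesh_small.triangles)

    def test_off_round_trip(self, tmp_path, biconcave_mesh_small):
        p = tmp_path / "cell.off"
        write_off(str(p), biconcave_mesh_small.vertices, biconcave_mesh_small.triangles)
        verts, tris = read_off(str(p))
        assert np.array_equal(verts, biconcave_mesh_small.vertices)
        assert np.array_equal(tris, biconcave_mesh_small.triangles)

    def test_off_opens_in_independent_reader(self, tmp_path, biconcave_mesh_small):
        trimesh = pytest.importorskip("trimesh")
        p = tmp_path / "cell.off"
        write_off(str(p), biconcave_mesh_small.vertices, biconcave_mesh_small.triangles)
        tm = trimesh.load(str(p), process=False)
        assert tm.is_watertight
        assert len(tm.vertices) == biconcave_mesh_small.n_vertices

    def test_vtk_2d_contours_embedded(self, tmp_path):
        from splenosim.engine import rbc_outline_2d

        out = rbc_outline_2d("sickle", 24)
        p = tmp_path / "contour.vtk"
        write_vtk_polydata(str(p), out, [np.arange(24)])
        verts, polys = read_vtk_polydata(str(p))
        assert verts.shape == (24, 3)
        assert np.allclose(verts[:, 2], 0.0)


class TestSummary:
    def test_validate_and_write(self, tmp_path):
        from splenosim.protocols import AssayResult

        series = RetentionTimeSeries(np.linspace(0, 1, 5), np.arange(5), np.zeros(5))
        res = AssayResult(
            assay="toy", config_hash="abc", seeds=[1],
            series=[series], criterion=RetentionCriterion(),
        )
        paths = write_outputs(res, str(tmp_path / "out"))
        assert set(paths) == {"series_seed1", "summary"}

    def test_schema_violations_raise(self):
        with pytest.raises(ValueError):
            validate_summary({"assay": "x"})
        with pytest.raises(TypeError):
            validate_summary({
                "assay": 1, "config_hash": "h", "seeds": [], "plateau_count": 0,
                "plateau_reached": True, "criterion": {},
            })
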