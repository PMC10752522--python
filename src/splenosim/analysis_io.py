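"""Retention counting, suspension statistics, and file I/O.

Counting is a pure function of (trajectory, criterion): a cell is retained
at time t if it has held at least ``min_bond_count`` live bonds continuously
for ``min_bound_duration`` and its centroid speed is below
``max_centroid_speed`` — the programmatic counterpart of the visual "firmly
adhered" classification. Exported series (CSV) round-trip losslessly through
this module's readers; mesh snapshots are written as legacy ASCII VTK
polydata and OFF.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RetentionCriterion",
    "RetentionTimeSeries",
    "count_retained",
    "mean_suspension_velocity",
    "write_outputs",
    "write_csv_series",
    "read_csv_series",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_off",
    "read_off",
    "SUMMARY_SCHEMA",
    "validate_summary",
]


@dataclass(frozen=True)
class RetentionCriterion:
    """Thresholds defining a "retained" cell."""

    min_bond_count: int = 1
    min_bound_duration: float = 0.05  # s (reported time units)
    max_centroid_speed: float = 15.0  # μm/s

    def __post_init__(self) -> None:
        if self.min_bond_count < 0 or self.min_bound_duration < 0 or self.max_centroid_speed < 0:
            raise ValueError("criterion thresholds must be nonnegative")

    @classmethod
    def for_bulk_velocity(cls, u_bulk: float, **kw) -> "RetentionCriterion":
        """Default criterion: centroid slower than 10% of the bulk flow."""
        return cls(max_centroid_speed=0.1 * u_bulk, **kw)


@dataclass
class RetentionTimeSeries:
    """Retained-cell count and mean suspension speed vs. time."""

    time: np.ndarray
    retained_count: np.ndarray
    mean_suspension_velocity: np.ndarray
    retained_mask: np.ndarray | None = None  # (T, C) per-cell flags

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.retained_count = np.asarray(self.retained_count, dtype=np.int64)
        self.mean_suspension_velocity = np.asarray(
            self.mean_suspension_velocity, dtype=np.float64
        )
        if np.any(self.retained_count < 0):
            raise ValueError("retained count must be nonnegative")


def count_retained(trajectory, criterion: RetentionCriterion) -> RetentionTimeSeries:
    """Evaluate the retention criterion on a recorded trajectory.

    ``trajectory`` needs ``times``, ``bond_counts`` (T, C) and
    ``cell_speeds`` (T, C); raises ``ValueError`` if the bond channel is
    missing. Pure: re-running never changes the result.
    """
    arrs = trajectory.as_arrays() if hasattr(trajectory, "as_arrays") else trajectory
    times = np.asarray(arrs["times"], dtype=np.float64)
    if "bond_counts" not in arrs or len(arrs["bond_counts"]) == 0:
        raise ValueError("trajectory lacks a bond-count channel")
    bonds = np.asarray(arrs["bond_counts"])
    speeds = np.asarray(arrs["cell_speeds"])
    n_t, n_c = bonds.shape
    # centroid-displacement speed over a ~0.1 s window suppresses the thermal
    # noise of instantaneous vertex velocities
    if "centroids" in arrs and len(arrs["centroids"]) == n_t and n_t > 1:
        cent = np.asarray(arrs["centroids"])
        dt_rec = max(np.median(np.diff(times)), 1e-12)
        w = max(int(round(0.1 / dt_rec)), 1)
        disp = np.empty((n_t, n_c))
        for k in range(n_t):
            k0 = max(k - w, 0)
            span = max(times[k] - times[k0], dt_rec)
            disp[k] = np.linalg.norm(cent[k] - cent[k0], axis=-1) / span
        disp[0] = speeds[0]
        speeds = disp
    bound = bonds >= criterion.min_bond_count
    retained = np.zeros((n_t, n_c), dtype=bool)
    streak_start = np.full(n_c, np.nan)
    for k in range(n_t):
        newly = bound[k] & np.isnan(streak_start)
        streak_start[newly] = times[k]
        streak_start[~bound[k]] = np.nan
        ok_duration = bound[k] & (times[k] - streak_start >= criterion.min_bound_duration)
        retained[k] = ok_duration & (speeds[k] < criterion.max_centroid_speed)
    counts = retained.sum(axis=1)
    mean_v = speeds.mean(axis=1) if n_c else np.zeros(n_t)
    return RetentionTimeSeries(times, counts, mean_v, retained_mask=retained)


def mean_suspension_velocity(trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Mean centroid speed over all cells (free and retained) per snapshot."""
    arrs = trajectory.as_arrays() if hasattr(trajectory, "as_arrays") else trajectory
    speeds = np.asarray(arrs["cell_speeds"])
    if speeds.size == 0:
        raise ValueError("trajectory contains no cells")
    return np.asarray(arrs["times"], dtype=np.float64), speeds.mean(axis=1)


# ---------------------------------------------------------------------------
# CSV (RFC-4180, lossless round trip)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def write_csv_series(path: str, series: RetentionTimeSeries, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(path)
    lines = ["time_s,retained_count,mean_suspension_velocity_um_s"]
    for t, c, v in zip(series.time, series.retained_count, series.mean_suspension_velocity):
        lines.append(f"{_fmt(t)},{int(c)},{_fmt(v)}")
    with open(path, "w", newline="") as f:
        f.write("\r\n".join(lines) + "\r\n")


def read_csv_series(path: str) -> RetentionTimeSeries:
    with open(path, newline="") as f:
        rows = [ln.strip() for ln in f if ln.strip()]
    t, c, v = [], [], []
    for row in rows[1:]:
        a, b, d = row.split(",")
        t.append(float(a))
        c.append(int(b))
        v.append(float(d))
    return RetentionTimeSeries(np.array(t), np.array(c), np.array(v))


# ---------------------------------------------------------------------------
# JSON summary + shipped schema
# ---------------------------------------------------------------------------

#: Declarative summary schema: required keys and their types.
SUMMARY_SCHEMA: dict[str, type | tuple] = {
    "assay": str,
    "config_hash": str,
    "seeds": list,
    "plateau_count": (int, float, type(None)),
    "plateau_reached": bool,
    "criterion": dict,
}


def validate_summary(summary: dict) -> None:
    """Check the summary dict against :data:`SUMMARY_SCHEMA` (raises)."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise TypeError(f"summary[{key!r}] has type {type(summary[key]).__name__}")


def write_outputs(result, out_dir: str, overwrite: bool = False,
                  snapshots=None) -> dict[str, str]:
    """Write an assay result: per-seed CSV series, a JSON summary, and
    optional VTK polydata snapshots (sequence of (vertices, polygons)).

    Returns the mapping of artefact names to paths. Raises on path
    collisions unless ``overwrite``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for k, (verts, polys) in enumerate(snapshots or []):
        p = os.path.join(out_dir, f"snapshot_{k:04d}.vtk")
        write_vtk_polydata(p, verts, polys, overwrite=overwrite)
        paths[f"snapshot_{k:04d}"] = p
    for seed, series in zip(result.seeds, result.series):
        p = os.path.join(out_dir, f"series_seed{seed}.csv")
        write_csv_series(p, series, overwrite=overwrite)
        paths[f"series_seed{seed}"] = p
    summary = result.summary()
    validate_summary(summary)
    p = os.path.join(out_dir, "summary.json")
    if os.path.exists(p) and not overwrite:
        raise FileExistsError(p)
    with open(p, "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    paths["summary"] = p
    return paths


# ---------------------------------------------------------------------------
# VTK legacy polydata and OFF
# ---------------------------------------------------------------------------


def write_vtk_polydata(path: str, vertices: np.ndarray, polygons: np.ndarray,
                       overwrite: bool = False) -> None:
    """Legacy ASCII VTK polydata (triangles or general polygons)."""
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(path)
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.shape[1] == 2:  # embed 2D contours in the z = 0 plane
        vertices = np.column_stack([vertices, np.zeros(len(vertices))])
    polys = [np.asarray(p, dtype=np.int64) for p in polygons]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nsplenosim surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} double\n")
        for v in vertices:
            f.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
        total = sum(len(p) + 1 for p in polys)
        f.write(f"POLYGONS {len(polys)} {total}\n")
        for p in polys:
            f.write(" ".join([str(len(p))] + [str(int(i)) for i in p]) + "\n")


def read_vtk_polydata(path: str) -> tuple[np.ndarray, list[np.ndarray]]:
    with open(path) as f:
        tokens = f.read().split()
    i = tokens.index("POINTS")
    n_pts = int(tokens[i + 1])
    vals = tokens[i + 3 : i + 3 + 3 * n_pts]
    vertices = np.array(vals, dtype=np.float64).reshape(n_pts, 3)
    j = tokens.index("POLYGONS")
    n_poly = int(tokens[j + 1])
    polys = []
    k = j + 3
    for _ in range(n_poly):
        cnt = int(tokens[k])
        polys.append(np.array(tokens[k + 1 : k + 1 + cnt], dtype=np.int64))
        k += cnt + 1
    return vertices, polys


def write_off(path: str, vertices: np.ndarray, triangles: np.ndarray,
              overwrite: bool = False) -> None:
    """Object File Format writer for triangle meshes."""
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(path)
    vertices = np.asarray(vertices, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.int64)
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{len(vertices)} {len(triangles)} 0\n")
        for v in vertices:
            f.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
        for t in triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as f:
        tokens = f.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    k = 4
    vertices = np.array(tokens[k : k + 3 * nv], dtype=np.float64).reshape(nv, 3)
    k += 3 * nv
    tris = []
    for _ in range(nf):
        cnt = int(tokens[k])
        tris.append([int(x) for x in tokens[k + 1 : k + 1 + cnt]])
        k += cnt + 1
    return vertices, np.asarray(tris, dtype=np.int64)
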