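"""Membrane-deformation statistic and protein-membrane distance series.

Operates on coordinate snapshots (e.g. lipid-headgroup beads exported from a
coarse-grained simulation, or synthetic surfaces).  The deformation index
tiles the x-y plane into square patches, fits a plane to the points of each
occupied patch by total least squares, and averages the absolute dot product
between the patch normals and the z axis: 1 for a flat bilayer, smaller the
more the membrane bends.  The distance series reports, per frame, the
minimum Euclidean distance between any protein point and any membrane
point, honouring periodic images in x and y when box extents are given.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MembraneError(ValueError):
    pass


@dataclass
class MembraneFrame:
    """One coordinate snapshot: membrane points, protein points, optional box."""

    time: float
    membrane_points: np.ndarray  # (n, 3)
    protein_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    box: tuple[float, float] | None = None  # (Lx, Ly) periodic extents

    def __post_init__(self) -> None:
        self.membrane_points = np.asarray(self.membrane_points, dtype=float).reshape(-1, 3)
        self.protein_points = np.asarray(self.protein_points, dtype=float).reshape(-1, 3)
        if len(self.membrane_points) < 3:
            raise MembraneError("a frame needs at least 3 membrane points")
        if not (
            np.isfinite(self.membrane_points).all()
            and np.isfinite(self.protein_points).all()
        ):
            raise MembraneError("coordinates must be finite")


@dataclass
class DeformationResult:
    D: float  # mean |n . z| over occupied patches, in [0, 1]
    normals: np.ndarray  # (n_patches, 3) unit normals, oriented to +z
    grid_shape: tuple[int, int]
    n_skipped: int  # patches with < 3 points or a degenerate fit


def _patch_normal(points: np.ndarray) -> np.ndarray | None:
    """Total-least-squares plane normal (smallest principal direction)."""
    if len(points) < 3:
        return None
    centred = points - points.mean(axis=0)
    # singular values sorted descending; degenerate if rank < 2
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= max(s[0], 1.0) * 1e-12:
        return None  # collinear points: normal undefined
    n = vt[-1]
    return n if n[2] >= 0 else -n


def deformation_index(frame: MembraneFrame, patch_size: float) -> DeformationResult:
    """Tile x-y into ``patch_size`` squares and average |normal . z|."""
    if patch_size <= 0:
        raise MembraneError("patch_size must be positive")
    pts = frame.membrane_points
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    ix = np.floor((pts[:, 0] - x0) / patch_size).astype(int)
    iy = np.floor((pts[:, 1] - y0) / patch_size).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    normals = []
    n_skipped = 0
    for key in np.unique(ix * ny + iy):
        patch = pts[ix * ny + iy == key]
        n = _patch_normal(patch)
        if n is None:
            n_skipped += 1
        else:
            normals.append(n)
    if not normals:
        raise MembraneError("all patches degenerate (empty or collinear)")
    normals = np.vstack(normals)
    D = float(np.mean(np.abs(normals[:, 2])))
    return DeformationResult(D=D, normals=normals, grid_shape=(int(nx), int(ny)), n_skipped=n_skipped)


def min_distance(frame: MembraneFrame) -> float:
    """Minimum distance between any protein point and any membrane point."""
    if len(frame.protein_points) == 0:
        raise MembraneError("frame has no protein points")
    diff = frame.protein_points[:, None, :] - frame.membrane_points[None, :, :]
    if frame.box is not None:
        for axis, L in enumerate(frame.box):
            diff[:, :, axis] -= np.round(diff[:, :, axis] / L) * L
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def min_distance_series(frames: list[MembraneFrame]) -> list[tuple[float, float]]:
    """Per-frame (time, minimum protein-membrane distance)."""
    return [(f.time, min_distance(f)) for f in frames]


def deformation_series(frames: list[MembraneFrame], patch_size: float) -> list[tuple[float, float]]:
    return [(f.time, deformation_index(f, patch_size).D) for f in frames]


def read_frames_csv(path: str | Path) -> list[MembraneFrame]:
    """Read frames from CSV with columns: frame, role{membrane,protein}, x, y, z.

    Optional columns ``box_x``/``box_y`` (constant within a frame) set the
    periodic extents.
    """
    rows_by_frame: dict[float, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            t = float(row["frame"])
            entry = rows_by_frame.setdefault(t, {"membrane": [], "protein": [], "box": None})
            role = row["role"].strip().lower()
            if role not in ("membrane", "protein"):
                raise MembraneError(f"unknown role {row['role']!r}")
            entry[role].append((float(row["x"]), float(row["y"]), float(row["z"])))
            if row.get("box_x") and row.get("box_y"):
                entry["box"] = (float(row["box_x"]), float(row["box_y"]))
    frames = []
    for t in sorted(rows_by_frame):
        e = rows_by_frame[t]
        frames.append(
            MembraneFrame(
                time=t,
                membrane_points=np.array(e["membrane"]).reshape(-1, 3),
                protein_points=np.array(e["protein"]).reshape(-1, 3) if e["protein"] else np.empty((0, 3)),
                box=e["box"],
            )
        )
    return frames
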