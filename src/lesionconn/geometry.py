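"""Exact streamline-voxel intersection geometry.

Streamlines are polylines in world millimetres; voxels are axis-aligned unit
cubes in voxel space, related to world space by a NIfTI-style affine.  The
central quantity is the segment length ``l(i, v)``: how many millimetres of
streamline ``i`` lie inside voxel ``v``.  These lengths populate the columns
of the signal forward operator and the denominator of the per-voxel relative
signal reduction.

Conventions
-----------
* Voxel index ``k`` owns the half-open interval ``[k, k + 1)`` along each
  axis of voxel space; a point exactly on an interior face belongs to the
  higher-index voxel.
* A point exactly on the *outer* face of the grid is clipped into the last
  voxel, so streamlines may span whole boundary voxels (entry and exit on
  voxel faces) without leaving the grid.
* Zero-length polyline segments (repeated points) are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SegmentTable", "traverse", "visited_voxels", "default_affine"]

_EPS = 1e-12


def default_affine(voxel_size: float = 1.0) -> np.ndarray:
    """Scaling affine mapping voxel coordinates to world mm (no rotation)."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size)
    return aff


@dataclass
class SegmentTable:
    """Sparse table of (streamline, voxel, length) intersection records.

    ``voxel`` holds linear (C-order raveled) voxel indices on ``grid_shape``.
    Lengths are in world millimetres; records for the same (streamline,
    voxel) pair are pre-summed.
    """

    streamline: np.ndarray
    voxel: np.ndarray
    length: np.ndarray
    grid_shape: tuple[int, int, int]
    n_streamlines: int = 0

    def __post_init__(self) -> None:
        self.streamline = np.asarray(self.streamline, dtype=np.int64)
        self.voxel = np.asarray(self.voxel, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.float64)
        if np.any(self.length <= 0):
            raise ValueError("segment lengths must be strictly positive")
        n_vox = int(np.prod(self.grid_shape))
        if self.voxel.size and (self.voxel.min() < 0 or self.voxel.max() >= n_vox):
            raise ValueError("voxel index outside the grid")
        if self.n_streamlines == 0 and self.streamline.size:
            self.n_streamlines = int(self.streamline.max()) + 1

    def __len__(self) -> int:
        return self.streamline.size


def _to_voxel_coords(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def _check_inside(vox_pts: np.ndarray, grid_shape: Sequence[int]) -> None:
    shape = np.asarray(grid_shape, dtype=np.float64)
    bad = np.any((vox_pts < -_EPS) | (vox_pts > shape + _EPS), axis=1)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"streamline point {idx} at voxel coordinates "
            f"{vox_pts[idx].tolist()} lies outside the grid {tuple(grid_shape)}"
        )


def point_to_voxel(point_world: np.ndarray, grid_shape: Sequence[int],
                   affine: np.ndarray) -> tuple[int, int, int]:
    """Voxel index containing a world-mm point (outer boundary clipped)."""
    v = _to_voxel_coords(point_world, affine)[0]
    _check_inside(v[None, :], grid_shape)
    ijk = np.floor(v).astype(np.int64)
    ijk = np.clip(ijk, 0, np.asarray(grid_shape) - 1)
    return tuple(int(k) for k in ijk)


def _walk(points, grid_shape, affine):
    """Yield (ijk, length_mm, t_entry) subsegments in traversal order.

    ``t_entry`` is the cumulative arc-length fraction at which the subsegment
    starts.  Consecutive subsegments in the same voxel are NOT merged here.
    """
    pts_w = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts_w.shape[0] < 2:
        raise ValueError("a streamline needs at least 2 points")
    if not np.all(np.isfinite(pts_w)):
        raise ValueError("streamline contains non-finite coordinates")
    pts_v = _to_voxel_coords(pts_w, affine)
    _check_inside(pts_v, grid_shape)

    seg_len = np.linalg.norm(np.diff(pts_w, axis=0), axis=1)
    total = float(seg_len.sum())
    if total <= 0.0:
        return
    shape = np.asarray(grid_shape, dtype=np.int64)
    cum = 0.0
    for a, b, L in zip(pts_v[:-1], pts_v[1:], seg_len):
        if L <= 0.0:
            continue
        d = b - a
        # parameters where the segment crosses integer planes on any axis
        breaks = [0.0, 1.0]
        for ax in range(3):
            if abs(d[ax]) < _EPS:
                continue
            lo, hi = sorted((a[ax], b[ax]))
            for k in range(int(np.ceil(lo + _EPS)), int(np.floor(hi - _EPS)) + 1):
                t = (k - a[ax]) / d[ax]
                if _EPS < t < 1.0 - _EPS:
                    breaks.append(t)
        breaks = np.unique(np.asarray(breaks))
        for t0, t1 in zip(breaks[:-1], breaks[1:]):
            if t1 - t0 <= _EPS:
                continue
            mid = a + 0.5 * (t0 + t1) * d
            ijk = np.clip(np.floor(mid).astype(np.int64), 0, shape - 1)
            yield tuple(int(k) for k in ijk), float((t1 - t0) * L), cum + t0 * L
        cum += float(L)


def traverse(points, grid_shape, voxel_size: float = 1.0,
             affine: np.ndarray | None = None,
             streamline_index: int = 0) -> SegmentTable:
    """Clip one streamline against the voxel grid.

    Returns a :class:`SegmentTable` whose rows give the total length (mm) of
    the streamline inside each voxel it intersects; multiple visits to the
    same voxel are summed.  Raises ``ValueError`` (naming the offending
    point) if any point falls outside the grid.
    """
    if affine is None:
        affine = default_affine(voxel_size)
    acc: dict[tuple[int, int, int], float] = {}
    for ijk, length, _ in _walk(points, grid_shape, affine):
        acc[ijk] = acc.get(ijk, 0.0) + length
    if not acc:
        return SegmentTable(np.empty(0, int), np.empty(0, int), np.empty(0),
                            tuple(grid_shape), n_streamlines=streamline_index + 1)
    voxels = np.array([np.ravel_multi_index(k, grid_shape) for k in acc])
    order = np.argsort(voxels)
    lengths = np.array(list(acc.values()))[order]
    return SegmentTable(
        np.full(len(acc), streamline_index), voxels[order], lengths,
        tuple(grid_shape), n_streamlines=streamline_index + 1)


def traverse_all(streamlines, grid_shape, voxel_size: float = 1.0,
                 affine: np.ndarray | None = None) -> SegmentTable:
    """Segment table for a whole tractogram (streamlines indexed 0..n-1)."""
    if affine is None:
        affine = default_affine(voxel_size)
    parts = [traverse(s, grid_shape, affine=affine, streamline_index=i)
             for i, s in enumerate(streamlines)]
    if not parts:
        return SegmentTable(np.empty(0, int), np.empty(0, int), np.empty(0),
                            tuple(grid_shape), n_streamlines=0)
    return SegmentTable(
        np.concatenate([p.streamline for p in parts]),
        np.concatenate([p.voxel for p in parts]),
        np.concatenate([p.length for p in parts]),
        tuple(grid_shape), n_streamlines=len(parts))


def visited_voxels(points, grid_shape, voxel_size: float = 1.0,
                   affine: np.ndarray | None = None
                   ) -> list[tuple[tuple[int, int, int], float]]:
    """Ordered voxel visits with entry parameter t in [0, 1].

    ``t`` is the cumulative arc-length fraction at which the voxel is first
    entered; consecutive subsegments in the same voxel are merged, but a
    voxel re-entered later appears again (order preserved).  A zero-length
    streamline that still has >= 2 (coincident) points reports its single
    voxel at t = 0.
    """
    if affine is None:
        affine = default_affine(voxel_size)
    pts_w = np.atleast_2d(np.asarray(points, dtype=np.float64))
    total = float(np.linalg.norm(np.diff(pts_w, axis=0), axis=1).sum())
    if total <= 0.0:
        return [(point_to_voxel(pts_w[0], grid_shape, affine), 0.0)]
    visits: list[tuple[tuple[int, int, int], float]] = []
    for ijk, _, s in _walk(pts_w, grid_shape, affine):
        if not visits or visits[-1][0] != ijk:
            visits.append((ijk, s / total))
    return visits
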