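"""Relative signal reduction and weakest-link weight adjustment.

After the augmented fit, each lesioned voxel ``v`` carries an absolute
signal loss ``xL_{k(v)}``.  The surviving fraction of intra-axonal signal is

    R(v) = (sum_i x_i l(i, v) - xL_{k(v)}) / sum_i x_i l(i, v)

over the streamlines traversing ``v``; R(v) = 1 for healthy voxels and 0
for complete axonal damage.  A streamline's cross-sectional area is then
allowed to vary along its course, c'_i(t) = c_i R(s_i(t)), and its adjusted
weight is the minimum along the path — the connection is only as strong as
its weakest link:

    c_hat_i = min_t c'_i(t) = c_i * min_{v visited} R(v).

R is piecewise-constant per voxel, so the continuous minimum equals the
minimum over the discrete visited-voxel set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import geometry
from .forward_model import AugmentedOperator, FitResult
from .geometry import SegmentTable

__all__ = ["ReductionMap", "AdjustedWeights", "reduction_map", "adjust_weights"]

logger = logging.getLogger(__name__)


@dataclass
class ReductionMap:
    """Per-voxel surviving signal fraction R in [0, 1] (1 outside lesions)."""

    R: np.ndarray
    lesion_voxels: np.ndarray  # linear indices the map was fitted on

    def __post_init__(self) -> None:
        if np.any(self.R < 0) or np.any(self.R > 1):
            raise ValueError("R must lie in [0, 1]")


@dataclass
class AdjustedWeights:
    c: np.ndarray
    c_hat: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.c_hat > self.c + 1e-12) or np.any(self.c_hat < 0):
            raise ValueError("adjusted weights must satisfy 0 <= c_hat <= c")


def reduction_map(result: FitResult, segments: SegmentTable,
                  operator: AugmentedOperator) -> ReductionMap:
    """Relative signal reduction per voxel from an augmented fit.

    For each lesioned voxel the fitted tractogram signal
    ``sum_i x_i l(i, v)`` is compared with the fitted loss ``xL_{k(v)}``;
    the ratio is clamped into [0, 1] (a loss overshooting the coverage, as
    can happen under noise, maps to 0).  A lesioned voxel traversed by no
    streamline has an undefined ratio; no weight can be modulated there, so
    R is set to 1 and a warning is logged.
    """
    grid_shape = operator.grid_shape or segments.grid_shape
    R = np.ones(int(np.prod(grid_shape)), dtype=np.float64)
    if operator.n_lesion_voxels == 0:
        return ReductionMap(R=R.reshape(grid_shape),
                            lesion_voxels=np.empty(0, dtype=np.int64))
    # fitted per-voxel tractogram signal, restricted to lesioned voxels
    coverage = operator.A @ result.x
    for v, col in operator.k.items():
        denom = coverage[v]
        if denom <= 0.0:
            logger.warning(
                "lesioned voxel %d has no streamline coverage; R set to 1", v)
            continue
        R[v] = min(1.0, max(0.0, (denom - result.xL[col]) / denom))
    return ReductionMap(R=R.reshape(grid_shape),
                        lesion_voxels=operator.lesion_voxels)


def adjust_weights(weights: np.ndarray, streamlines, reduction: ReductionMap,
                   voxel_size: float = 1.0,
                   affine: np.ndarray | None = None) -> AdjustedWeights:
    """Weakest-link adjustment of streamline weights.

    ``c_hat_i = c_i * min R(v)`` over the voxels streamline ``i`` visits.
    With an all-ones reduction map (empty lesion mask) this is the identity.
    """
    weights = np.asarray(weights, dtype=np.float64)
    R = np.asarray(reduction.R)
    grid_shape = R.shape
    if affine is None:
        affine = geometry.default_affine(voxel_size)
    c_hat = np.empty_like(weights)
    for i, pts in enumerate(streamlines):
        visits = geometry.visited_voxels(pts, grid_shape, affine=affine)
        rmin = min(R[ijk] for ijk, _ in visits)
        c_hat[i] = weights[i] * rmin
    return AdjustedWeights(c=weights, c_hat=c_hat)
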