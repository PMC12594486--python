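"""Signal forward operator, lesion augmentation, and non-negative fitting.

The measured intra-axonal signal-fraction map ``y`` is modelled voxelwise as
a non-negative linear combination of streamline contributions::

    x = argmin_{x >= 0} || A x - y ||^2

where ``A[v, i] = l(i, v)`` is the length of streamline ``i`` inside voxel
``v``.  In pathological tissue this model cannot represent the local signal
loss, so the operator is augmented with one extra column per lesioned voxel,
holding a single ``-1`` entry at that voxel::

    [x | xL] = argmin_{x, xL >= 0} || [A | L] [x | xL] - y ||^2

The non-negative coefficient ``xL_k`` then expresses the *absolute* signal
loss inside its voxel, decoupling axonal contributions from tissue damage
and preventing the global fit from compensating for the lesion by biasing
streamline weights elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .geometry import SegmentTable

__all__ = ["AugmentedOperator", "FitResult", "build_operator",
           "augment_with_lesions", "fit", "residual_rmse_map"]


def build_operator(segments: SegmentTable, n_voxels: int | None = None,
                   n_streamlines: int | None = None) -> sp.csr_matrix:
    """Assemble the sparse operator A (n_voxels x n_streamlines).

    Entry (v, i) is the total intersection length ``l(i, v)``; duplicate
    records are summed by the sparse constructor.
    """
    if n_voxels is None:
        n_voxels = int(np.prod(segments.grid_shape))
    if n_streamlines is None:
        n_streamlines = segments.n_streamlines
    if np.any(segments.length < 0):
        raise ValueError("negative segment length")
    if segments.voxel.size and segments.voxel.max() >= n_voxels:
        raise ValueError("voxel index out of bounds")
    if segments.streamline.size and segments.streamline.max() >= n_streamlines:
        raise ValueError("streamline index out of bounds")
    A = sp.coo_matrix(
        (segments.length, (segments.voxel, segments.streamline)),
        shape=(n_voxels, n_streamlines))
    return A.tocsr()


@dataclass
class AugmentedOperator:
    """Block operator [A | L] with the voxel -> lesion-column map ``k``."""

    A: sp.csr_matrix
    L: sp.csr_matrix
    k: dict[int, int]  # linear voxel index -> column of L
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_voxels(self) -> int:
        return self.A.shape[0]

    @property
    def n_streamlines(self) -> int:
        return self.A.shape[1]

    @property
    def n_lesion_voxels(self) -> int:
        return self.L.shape[1]

    @property
    def lesion_voxels(self) -> np.ndarray:
        return np.fromiter(self.k.keys(), dtype=np.int64, count=len(self.k))

    def matrix(self) -> sp.csr_matrix:
        if self.n_lesion_voxels == 0:
            return self.A
        return sp.hstack([self.A, self.L]).tocsr()


def augment_with_lesions(A: sp.spmatrix,
                         lesion_mask: np.ndarray | None,
                         grid_shape: tuple[int, int, int] | None = None
                         ) -> AugmentedOperator:
    """Append one -1 column per lesioned voxel, ascending voxel order.

    An empty (or None) mask yields L with zero columns, i.e. the standard
    operator unchanged.
    """
    A = sp.csr_matrix(A)
    n_voxels = A.shape[0]
    if lesion_mask is None:
        voxels = np.empty(0, dtype=np.int64)
    else:
        mask = np.asarray(lesion_mask).astype(bool)
        if grid_shape is None:
            grid_shape = mask.shape
        if int(np.prod(mask.shape)) != n_voxels:
            raise ValueError("lesion mask grid does not match the operator")
        voxels = np.flatnonzero(mask.ravel(order="C"))
    L = sp.coo_matrix(
        (-np.ones(voxels.size), (voxels, np.arange(voxels.size))),
        shape=(n_voxels, voxels.size)).tocsr()
    k = {int(v): j for j, v in enumerate(voxels)}
    return AugmentedOperator(A=A, L=L, k=k, grid_shape=grid_shape)


@dataclass
class FitResult:
    """Solution of the (augmented) non-negative least-squares problem.

    ``residual`` is the full per-voxel misfit ``y - [A|L][x|xL]``;
    ``objective`` sums squared residuals over the system rows actually
    fitted (voxels with streamline coverage or a lesion column — rows with
    neither only add a constant and are dropped from the solve).
    """

    x: np.ndarray
    xL: np.ndarray
    residual: np.ndarray
    objective: float
    rows: np.ndarray = field(default=None, repr=False)  # fitted-row mask

    def __post_init__(self) -> None:
        if np.any(self.x < 0) or np.any(self.xL < 0):
            raise ValueError("non-negativity violated")


def fit(operator: AugmentedOperator | sp.spmatrix, y: np.ndarray,
        tolerance: float | None = None) -> FitResult:
    """Solve argmin_{x>=0} ||Ax - y||^2 with the active-set NNLS solver.

    ``operator`` may be a plain sparse matrix (standard model) or an
    :class:`AugmentedOperator` (lesion compartment included).  The problem
    is convex; the Lawson-Hanson solver is deterministic for fixed inputs.
    """
    if not isinstance(operator, AugmentedOperator):
        operator = AugmentedOperator(
            A=sp.csr_matrix(operator),
            L=sp.csr_matrix((operator.shape[0], 0)), k={})
    y = np.asarray(y, dtype=np.float64).ravel(order="C")
    M = operator.matrix()
    if y.size != M.shape[0]:
        raise ValueError(
            f"y has {y.size} entries but the operator has {M.shape[0]} rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    covered = np.asarray((M != 0).sum(axis=1)).ravel() > 0
    rows = np.flatnonzero(covered)
    dense = M[rows].toarray()
    if tolerance is None:
        sol, _ = scipy.optimize.nnls(dense, y[rows])
    else:
        sol, _ = scipy.optimize.nnls(dense, y[rows], atol=tolerance)
    nstr = operator.n_streamlines
    x, xL = sol[:nstr], sol[nstr:]
    residual = y - M @ sol
    objective = float(np.sum(residual[rows] ** 2))
    return FitResult(x=x, xL=xL, residual=residual, objective=objective,
                     rows=covered)


def residual_rmse_map(result: FitResult, grid_shape: tuple[int, int, int],
                      block_size: int = 1) -> np.ndarray:
    """Per-voxel root-mean-square fitting error as a volume.

    With a single measurement per voxel (the signal-fraction map) the RMSE
    reduces to the absolute residual.  ``block_size`` is kept for the
    multi-measurement extension and must be 1 here.
    """
    if block_size != 1:
        raise NotImplementedError("only single-measurement data supported")
    return np.abs(result.residual).reshape(grid_shape)
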