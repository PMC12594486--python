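"""Connectome construction from weighted streamlines.

Nodes are the labels of an integer parcellation volume (0 = background);
each streamline is assigned to the edge joining the labels of its two
endpoint voxels.  The connection strength of an edge is the sum of the
weights of its streamlines: the original fitted weights ``c_i`` for the
standard connectome, or the weakest-link adjusted weights ``c_hat_i`` for
the multi-compartment variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

__all__ = ["Connectome", "assign_nodes", "build_connectome",
           "threshold_density"]


@dataclass
class Connectome:
    """Symmetric nonnegative node x node matrix (zero diagonal).

    Node ``n`` (1-based parcellation label) maps to row/column ``n - 1``.
    ``bundles`` maps each edge (a, b), a < b in label terms, to the indices
    of its streamlines.
    """

    matrix: np.ndarray
    variant: str = "standard"
    bundles: dict[tuple[int, int], list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=np.float64)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(M, M.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError("connectome diagonal must be zero")
        if np.any(M < 0):
            raise ValueError("connectome weights must be non-negative")
        self.matrix = M

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, k=1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) // 2
        return self.n_edges / possible if possible else 0.0


def assign_nodes(streamlines, parcellation: np.ndarray,
                 voxel_size: float = 1.0,
                 affine: np.ndarray | None = None
                 ) -> list[tuple[int, int] | None]:
    """Map each streamline to the labels of its endpoint voxels.

    A streamline whose endpoints land in background (label 0) or in the
    same parcel (self-loop) is marked unassigned (None).
    """
    parc = np.asarray(parcellation)
    if affine is None:
        affine = geometry.default_affine(voxel_size)
    out: list[tuple[int, int] | None] = []
    for pts in streamlines:
        pts = np.asarray(pts, dtype=np.float64)
        a = int(parc[geometry.point_to_voxel(pts[0], parc.shape, affine)])
        b = int(parc[geometry.point_to_voxel(pts[-1], parc.shape, affine)])
        if a == 0 or b == 0 or a == b:
            out.append(None)
        else:
            out.append((min(a, b), max(a, b)))
    return out


def build_connectome(weights: np.ndarray,
                     assignments: list[tuple[int, int] | None],
                     n_nodes: int, variant: str = "standard") -> Connectome:
    """Sum streamline weights per edge into a symmetric matrix."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.size != len(assignments):
        raise ValueError("weights and assignments are misaligned")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    M = np.zeros((n_nodes, n_nodes))
    bundles: dict[tuple[int, int], list[int]] = {}
    for i, edge in enumerate(assignments):
        if edge is None:
            continue
        a, b = edge
        if a < 1 or b > n_nodes:
            raise ValueError(f"node label {edge} outside 1..{n_nodes}")
        M[a - 1, b - 1] += weights[i]
        M[b - 1, a - 1] += weights[i]
        bundles.setdefault(edge, []).append(i)
    return Connectome(matrix=M, variant=variant, bundles=bundles)


def threshold_density(conn: Connectome, target_density: float) -> Connectome:
    """Keep the strongest edges up to the target network density.

    Edges are ranked by weight; the largest count not exceeding
    ``target * possible_edges`` is kept, except that ties at the cutoff
    weight are all kept (deterministic, possibly overshooting the target).
    """
    if not 0.0 < target_density <= 1.0:
        raise ValueError("target_density must lie in (0, 1]")
    n = conn.n_nodes
    possible = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    w = conn.matrix[iu]
    nz = w[w > 0]
    k_max = int(np.floor(target_density * possible))
    if nz.size <= k_max:
        return Connectome(conn.matrix.copy(), conn.variant, dict(conn.bundles))
    if k_max == 0:
        cutoff = np.inf
    else:
        cutoff = np.sort(nz)[::-1][k_max - 1]
    keep = conn.matrix >= cutoff
    M = np.where(keep, conn.matrix, 0.0)
    kept_edges = {e: idx for e, idx in conn.bundles.items()
                  if M[e[0] - 1, e[1] - 1] > 0}
    return Connectome(matrix=M, variant=conn.variant, bundles=kept_edges)
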