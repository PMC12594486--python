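"""End-to-end convenience drivers tying the stages together.

These functions chain geometry -> operator -> NNLS fit -> reduction map ->
weakest link -> connectome for in-memory inputs (arrays and streamline
lists), and compute per-subject metric tables for simulated cohorts.  The
CLI and the acceptance checks are thin callers of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectome as conn_mod
from . import forward_model as fm
from . import geometry, lesion_adjust, netmetrics, phantoms, stats_perm

__all__ = ["SubjectFit", "fit_subject", "build_connectomes",
           "cohort_metric_table", "cohort_sensitivity"]


@dataclass
class SubjectFit:
    """Everything estimated for one signal map + tractogram (+ lesions)."""

    segments: geometry.SegmentTable
    operator: fm.AugmentedOperator
    fit: fm.FitResult
    reduction: lesion_adjust.ReductionMap
    weights: lesion_adjust.AdjustedWeights


def fit_subject(signal: np.ndarray, streamlines, lesion_mask=None,
                voxel_size: float = 1.0, affine=None,
                tolerance: float | None = None) -> SubjectFit:
    """Fit streamline weights to a signal map, with optional lesion columns.

    With ``lesion_mask=None`` (or an empty mask) this is the standard fit
    and the adjusted weights equal the fitted ones.
    """
    grid_shape = signal.shape
    if affine is None:
        affine = geometry.default_affine(voxel_size)
    segments = geometry.traverse_all(streamlines, grid_shape, affine=affine)
    A = fm.build_operator(segments, n_streamlines=len(list(streamlines)))
    op = fm.augment_with_lesions(A, lesion_mask, grid_shape=grid_shape)
    result = fm.fit(op, signal.ravel(order="C"), tolerance=tolerance)
    reduction = lesion_adjust.reduction_map(result, segments, op)
    adjusted = lesion_adjust.adjust_weights(result.x, streamlines, reduction,
                                            affine=affine)
    return SubjectFit(segments=segments, operator=op, fit=result,
                      reduction=reduction, weights=adjusted)


def build_connectomes(sf: SubjectFit, streamlines, parcellation,
                      affine=None) -> dict[str, conn_mod.Connectome]:
    """Standard (c_i) and multi-compartment (c_hat_i) connectomes."""
    n_nodes = int(np.asarray(parcellation).max())
    assign = conn_mod.assign_nodes(streamlines, parcellation, affine=affine)
    return {
        "standard": conn_mod.build_connectome(
            sf.weights.c, assign, n_nodes, variant="standard"),
        "multicompartment": conn_mod.build_connectome(
            sf.weights.c_hat, assign, n_nodes, variant="multicompartment"),
    }


def cohort_metric_table(subjects, parcellation, with_lesions: bool = True,
                        affine=None, metrics=netmetrics.METRICS,
                        modularity_seed: int = 0) -> pd.DataFrame:
    """Per-subject global network metrics for a simulated cohort.

    For each subject two variants are computed: the *healthy* connectome
    built from the undamaged forward signal, and the *damaged* one built
    from the lesioned signal (fitted with the lesion compartment when
    ``with_lesions``; without it otherwise, emulating the standard
    pipeline).  Returns a tidy frame with columns
    (subject, variant, metric, value).
    """
    rows = []
    for s_idx, subj in enumerate(subjects):
        healthy_signal = _forward_signal(subj)
        pairs = [("healthy", healthy_signal, None)]
        mask = subj.lesion_mask if with_lesions else None
        pairs.append(("damaged", subj.signal, mask))
        for variant_name, signal, mask_used in pairs:
            sf = fit_subject(signal, subj.streamlines, mask_used,
                             affine=affine)
            conns = build_connectomes(sf, subj.streamlines, parcellation,
                                      affine=affine)
            key = "multicompartment" if with_lesions else "standard"
            C = conns[key]
            for metric in metrics:
                fn = getattr(netmetrics, metric)
                if metric == "modularity":
                    # profound damage can zero every edge of a small
                    # phantom; an edgeless graph has no community
                    # structure, so record Q = 0 rather than erroring
                    value = (0.0 if C.matrix.sum() == 0
                             else fn(C, rng=modularity_seed))
                else:
                    value = fn(C)
                rows.append((s_idx, variant_name, metric, value))
    return pd.DataFrame(rows,
                        columns=["subject", "variant", "metric", "value"])


def _forward_signal(subj: phantoms.CohortSubject) -> np.ndarray:
    segments = geometry.traverse_all(subj.streamlines, subj.signal.shape)
    A = fm.build_operator(segments, n_streamlines=len(subj.streamlines))
    return np.asarray(A @ subj.true_weights).reshape(subj.signal.shape)


def cohort_sensitivity(table: pd.DataFrame, metric: str,
                       damage_level: float, n_iterations: int = 5000,
                       inner_resamples: int = 1000,
                       rng=None) -> stats_perm.SensitivityResult:
    """Run the half-split permutation procedure on one metric column."""
    sub = table[table.metric == metric].pivot(
        index="subject", columns="variant", values="value")
    return stats_perm.sensitivity_experiment(
        sub["healthy"].to_numpy(), sub["damaged"].to_numpy(),
        n_iterations=n_iterations, inner_resamples=inner_resamples,
        rng=rng, metric=metric, damage_level=damage_level)
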