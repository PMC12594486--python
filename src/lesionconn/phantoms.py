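"""Synthetic phantoms, lesion masks, graded damage, and cohorts.

Everything the pipeline consumes — signal-fraction map, tractogram, lesion
mask, parcellation — can be generated here on a small voxel grid, so every
stage is testable without imaging data.

The canonical phantom is a crossing configuration of straight bundles: two
vertical bundles crossing a horizontal one, with known true weights
(0.16, 0.14, 0.14).  Bundles run through whole voxels (unit intersection
length per voxel), so a bundle's weight and the voxel signal share units and
the healthy signal map is an exact forward construction ``y = A x_true``.
A focal lesion halving the signal in one voxel of Bundle 2 (0.14 -> 0.07)
then reproduces, under the standard fit, the error-compensation cascade:
Bundle 2 underestimated at 0.115, Bundle 1 inflated to 0.165, and the
untouched Bundle 3 dragged down to 0.138.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .forward_model import build_operator

__all__ = ["BundleSpec", "Phantom", "DamageLevel", "DAMAGE_LEVELS",
           "make_fig2_phantom", "make_crossing_phantom",
           "generate_lesion_mask", "apply_damage", "synthesize_cohort",
           "CohortSubject"]

#: Canonical degeneration grades: none, mild, moderate, severe, profound.
DAMAGE_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class DamageLevel:
    """Fractional intra-axonal signal reduction inside lesions, in [0, 1]."""

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("damage fraction must lie in [0, 1]")


@dataclass
class BundleSpec:
    """A bundle of streamlines sharing one true weight (signal fraction /mm)."""

    streamlines: list[np.ndarray]
    true_weight: float

    def __post_init__(self) -> None:
        if self.true_weight < 0:
            raise ValueError("true_weight must be non-negative")


@dataclass
class Phantom:
    grid_shape: tuple[int, int, int]
    voxel_size: float
    wm_mask: np.ndarray
    parcellation: np.ndarray
    bundles: list[BundleSpec]

    @property
    def affine(self) -> np.ndarray:
        return geometry.default_affine(self.voxel_size)

    @property
    def streamlines(self) -> list[np.ndarray]:
        return [s for b in self.bundles for s in b.streamlines]

    @property
    def true_weights(self) -> np.ndarray:
        """Per-streamline true weights, aligned with :attr:`streamlines`."""
        return np.array([b.true_weight for b in self.bundles
                         for _ in b.streamlines])

    def segment_table(self) -> geometry.SegmentTable:
        return geometry.traverse_all(self.streamlines, self.grid_shape,
                                     affine=self.affine)

    def forward_signal(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Noiseless signal map y = A w (defaults to the true weights)."""
        if weights is None:
            weights = self.true_weights
        A = build_operator(self.segment_table())
        return np.asarray(A @ np.asarray(weights)).reshape(self.grid_shape)


def _line(p0, p1) -> np.ndarray:
    return np.array([p0, p1], dtype=np.float64)


def make_fig2_phantom(lesion: bool = True):
    """The canonical three-bundle crossing phantom.

    Grid 5 x 3 x 1, unit voxels.  Bundle 1 (true weight 0.16) runs
    horizontally through 5 voxels, 3 exclusive; Bundles 2 and 3 (0.14 each)
    run vertically through 3 voxels, crossing Bundle 1 at x=1 and x=3.  The
    lesion sits in the upper voxel of Bundle 2 and halves its signal
    (0.14 -> 0.07).

    Returns ``(phantom, signal_map, lesion_mask, truth_weights)``.
    """
    shape = (5, 3, 1)
    b1 = BundleSpec([_line((0.0, 1.5, 0.5), (5.0, 1.5, 0.5))], 0.16)
    b2 = BundleSpec([_line((1.5, 0.0, 0.5), (1.5, 3.0, 0.5))], 0.14)
    b3 = BundleSpec([_line((3.5, 0.0, 0.5), (3.5, 3.0, 0.5))], 0.14)

    wm = np.zeros(shape, dtype=bool)
    wm[:, 1, 0] = True            # horizontal bundle
    wm[1, :, 0] = wm[3, :, 0] = True

    parc = np.zeros(shape, dtype=np.int32)
    parc[0, 1, 0], parc[4, 1, 0] = 1, 2      # Bundle 1 termini
    parc[1, 0, 0], parc[1, 2, 0] = 3, 4      # Bundle 2 termini
    parc[3, 0, 0], parc[3, 2, 0] = 5, 6      # Bundle 3 termini

    phantom = Phantom(shape, 1.0, wm, parc, [b1, b2, b3])
    signal = phantom.forward_signal()

    mask = np.zeros(shape, dtype=bool)
    mask[1, 2, 0] = True          # upper voxel of Bundle 2
    if lesion:
        signal = apply_damage(signal, mask, DamageLevel(0.5))
    truth = np.array([0.16, 0.14, 0.14])
    return phantom, signal, mask, truth


def make_crossing_phantom(n_horizontal: int, n_vertical: int,
                          rng: np.random.Generator,
                          weight_range: tuple[float, float] = (0.05, 0.30)
                          ) -> Phantom:
    """Random grid of straight crossing bundles with known weights.

    ``n_horizontal`` bundles run along x on distinct rows and
    ``n_vertical`` along y on distinct columns; every bundle owns exclusive
    voxels (rows/columns extend one voxel past the crossings on each side),
    so the system is identifiable.  True weights are drawn uniformly from
    ``weight_range``.
    """
    if n_horizontal < 0 or n_vertical < 0 or n_horizontal + n_vertical == 0:
        raise ValueError("need at least one bundle")
    nx = 2 * n_vertical + 1
    ny = 2 * n_horizontal + 1
    shape = (nx, ny, 1)
    rows = 2 * np.arange(n_horizontal) + 1   # odd rows
    cols = 2 * np.arange(n_vertical) + 1     # odd columns
    bundles = []
    wm = np.zeros(shape, dtype=bool)
    for r in rows:
        w = float(rng.uniform(*weight_range))
        bundles.append(BundleSpec(
            [_line((0.0, r + 0.5, 0.5), (nx, r + 0.5, 0.5))], w))
        wm[:, r, 0] = True
    for c in cols:
        w = float(rng.uniform(*weight_range))
        bundles.append(BundleSpec(
            [_line((c + 0.5, 0.0, 0.5), (c + 0.5, ny, 0.5))], w))
        wm[c, :, 0] = True

    parc = np.zeros(shape, dtype=np.int32)
    label = 1
    for r in rows:
        parc[0, r, 0], parc[nx - 1, r, 0] = label, label + 1
        label += 2
    for c in cols:
        parc[c, 0, 0], parc[c, ny - 1, 0] = label, label + 1
        label += 2
    return Phantom(shape, 1.0, wm, parc, bundles)


def generate_lesion_mask(wm_mask: np.ndarray, target_fraction: float,
                         rng: np.random.Generator,
                         n_spheres: int = 3) -> np.ndarray:
    """Union of randomly dilated spheres covering >= target_fraction of WM.

    Sphere centroids are sampled uniformly among WM voxels; radii start at 0
    (the centroid voxel) and a randomly chosen sphere is dilated by one
    voxel-radius step at a time until the union covers the target fraction
    of the WM.  The mask is always a subset of the WM; overshoot above the
    target by at most one dilation increment is accepted.
    """
    wm = np.asarray(wm_mask).astype(bool)
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    n_wm = int(wm.sum())
    if n_wm == 0:
        raise ValueError("empty WM mask: no support for lesion centroids")
    mask = np.zeros(wm.shape, dtype=bool)
    if target_fraction == 0.0:
        return mask

    wm_idx = np.argwhere(wm)
    n_spheres = max(1, min(n_spheres, n_wm))
    centroids = wm_idx[rng.choice(n_wm, size=n_spheres, replace=False)]
    radii = np.zeros(n_spheres)

    grids = np.indices(wm.shape).reshape(3, -1).T  # voxel ijk coordinates
    dist2 = np.stack([((grids - c) ** 2).sum(axis=1) for c in centroids])
    dist2 = dist2.reshape(n_spheres, *wm.shape)

    def rebuild() -> np.ndarray:
        m = np.zeros(wm.shape, dtype=bool)
        for s in range(n_spheres):
            m |= dist2[s] <= radii[s] ** 2
        return m & wm

    mask = rebuild()
    target = target_fraction * n_wm
    while mask.sum() < target:
        radii[rng.integers(n_spheres)] += 1.0
        mask = rebuild()
    return mask


def apply_damage(signal_map: np.ndarray, lesion_mask: np.ndarray,
                 level: DamageLevel | float) -> np.ndarray:
    """Scale the signal inside the mask by (1 - fraction); identity outside."""
    if not isinstance(level, DamageLevel):
        level = DamageLevel(float(level))
    signal = np.asarray(signal_map, dtype=np.float64)
    mask = np.asarray(lesion_mask).astype(bool)
    if signal.shape != mask.shape:
        raise ValueError(
            f"signal grid {signal.shape} does not match mask grid {mask.shape}")
    out = signal.copy()
    out[mask] *= 1.0 - level.fraction
    return out


@dataclass
class CohortSubject:
    """One simulated subject: damaged signal, its lesion, and ground truth."""

    signal: np.ndarray
    lesion_mask: np.ndarray
    streamlines: list[np.ndarray]
    true_weights: np.ndarray
    damage: float


def synthesize_cohort(n_subjects: int, base_phantom: Phantom,
                      weight_cv: float, damage_level: float,
                      lesion_fraction: float,
                      rng: np.random.Generator,
                      n_spheres: int = 3) -> list[CohortSubject]:
    """Multi-subject cohort with controlled between-subject variability.

    Per subject the bundle true weights are drawn as ``base * (1 + eps)``
    with ``eps ~ Normal(0, weight_cv)`` truncated at 0, a fresh lesion mask
    is generated, and the signal is built by exact forward construction then
    damaged inside the lesion.  All randomness flows through ``rng``, so a
    fixed seed reproduces the cohort bitwise.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if weight_cv < 0:
        raise ValueError("weight_cv must be non-negative")
    base = np.array([b.true_weight for b in base_phantom.bundles])
    seg = base_phantom.segment_table()
    A = build_operator(seg)
    # expand bundle weights to per-streamline weights
    counts = [len(b.streamlines) for b in base_phantom.bundles]
    subjects = []
    for _ in range(n_subjects):
        eps = rng.normal(0.0, weight_cv, size=base.size) if weight_cv > 0 \
            else np.zeros(base.size)
        w_bundle = np.maximum(base * (1.0 + eps), 0.0)
        w = np.repeat(w_bundle, counts)
        signal = np.asarray(A @ w).reshape(base_phantom.grid_shape)
        if lesion_fraction > 0:
            mask = generate_lesion_mask(base_phantom.wm_mask, lesion_fraction,
                                        rng, n_spheres=n_spheres)
        else:
            mask = np.zeros(base_phantom.grid_shape, dtype=bool)
        damaged = apply_damage(signal, mask, DamageLevel(damage_level))
        subjects.append(CohortSubject(
            signal=damaged, lesion_mask=mask,
            streamlines=base_phantom.streamlines,
            true_weights=w, damage=damage_level))
    return subjects
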