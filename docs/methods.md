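# Methods

## Model

### Simplified forward model

The data vector `y` is a voxelwise intra-axonal signal-fraction map
("fiber-density" map) with a single measurement per voxel.  Each voxel's
value is modelled as the sum over traversing streamlines of
`weight × intersection length`:

    y_v ≈ Σ_i x_i l(i, v),      x ≥ 0.

This is the intra-axonal-only reduction of the full multi-compartment
tractography forward model; extra-axonal and isotropic compartments would
enter as additional column blocks of `A` and are a documented extension
point, not implemented.  Consequences of the single-measurement model:

* the per-voxel residual RMSE equals the absolute residual;
* voxels traversed by no streamline and holding no lesion column contribute
  a constant to the objective and are dropped from the solve (their residual
  is still reported).

### Lesion compartment

For every voxel of the binary WM-lesion mask one column with a single `-1`
entry is appended (ascending linear voxel order, C-order ravel).  Each
lesioned voxel is treated independently; there is no within-lesion coupling
or regularisation.  The coefficient `xL_{k(v)} ≥ 0` is the **absolute**
signal loss in voxel `v` (units of the signal map), not a loss per unit
length.  The augmented problem remains a convex NNLS; its feasible set
contains the standard one, so the augmented objective can never be worse.

### Solver

`scipy.optimize.nnls` (Lawson–Hanson active set): deterministic for fixed
inputs, exact on the noiseless phantoms to solver precision.  No
regularisation is applied by default; an `atol` pass-through exists for
degenerate systems.  Systems are densified for the solve — appropriate for
phantom-scale problems (thousands of rows); a sparse first-order solver
would be needed for whole-brain tractograms, which is out of scope.

### Reduction map and weakest link

`R(v) = (Σ_i x_i l(i,v) − xL_{k(v)}) / Σ_i x_i l(i,v)` on lesioned voxels,
1 elsewhere.  Numerical choices:

* `R` is clamped into [0, 1] after evaluation; a fitted loss overshooting
  the fitted coverage (possible under noise) maps to `R = 0`.
* A lesioned voxel with zero streamline coverage has an undefined ratio; no
  streamline weight could be modulated there anyway, so `R := 1` and a
  warning is logged.
* `R` is piecewise-constant per voxel, so the continuous minimum over the
  path parameter `t` equals the minimum over the discrete visited-voxel
  set; `ĉ_i = c_i · min R` is evaluated on that set.

### Geometry

Exact polyline–grid clipping: each segment is cut at integer-plane
crossings in voxel space; sub-segment ownership is decided by the midpoint
(half-open rule `[k, k+1)`, ties to the higher-index voxel).  Lengths are
accumulated in world mm, so per-streamline lengths sum to the polyline arc
length to 1e−9 relative.  One deliberate deviation from a strict half-open
grid: a point exactly on the **outer** face is clipped into the last voxel.
This lets phantom bundles span whole voxels (unit segment length per voxel,
which is what makes the worked example's printed numbers exact) while
keeping every interior tie deterministic.

### Connectome

Endpoint-voxel labelling assigns each streamline to the parcel labels of
its two endpoint voxels; background (label 0) endpoints and self-loops are
unassigned and excluded.  Edge weight = sum of streamline weights (fitted
`c_i` for the standard variant, adjusted `ĉ_i` for the multi-compartment
variant).  Density thresholding keeps the strongest edges up to the target
edge count and keeps all ties at the cutoff weight — deterministic, at the
price of possibly overshooting the exact target density.

### Network metrics

* mean strength: mean over nodes of summed incident weights (linear in a
  global weight factor);
* global efficiency: average inverse shortest-path length over ordered
  pairs with edge length = 1/weight (the common connectomics convention —
  the choice of mapping matters and is asserted in tests: efficiency scales
  linearly with a global weight factor); disconnected pairs contribute 0;
* modularity: Newman–Girvan weighted Q of the best partition over 10 seeded
  Louvain restarts (resolution 1).  Q is scale-invariant.  Louvain is a
  heuristic: tests assert `Q ≤` the exhaustive-search optimum, with
  equality verified on small graphs, not global optimality in general.

## Permutation sensitivity procedure

Every simulated subject has a healthy and a damaged connectome variant.
Per outer iteration the cohort is split at random into halves (odd cohorts:
the larger half becomes the control group); controls contribute
healthy-variant metric values, patients damaged-variant values, and a
two-sided difference-in-means permutation test is run (exact enumeration
when `C(n, n_a) ≤ 1e5`, else Monte-Carlo with add-one correction,
1,000 resamples by default).  The reported figure is the **proportion of
iterations with p > 0.05** over 5,000 outer iterations: ≈0.95 under the
null, falling toward 0 as damage becomes detectable.

## Synthetic data: what it emulates, what it does not

The generator emulates the four pipeline inputs directly in
signal-fraction space: straight crossing bundles through whole voxels with
known true weights, an exact forward-constructed (hence noiseless) signal
map, spherical lesion masks randomly dilated to a target WM fraction
(default 5 %), damage as fractional signal reduction at five grades
(0/25/50/75/100 %), and cohorts with multiplicative Gaussian
between-subject weight variability (CV 10 %, truncated at 0; 44 subjects
by default).  Defaults were fixed once from the stated experimental
conditions or, where unstated (CV, sphere count = 3), from what is typical
of tract-weight variability and desk-scale phantoms.

It does **not** emulate: diffusion-weighted signal formation (no b-values,
tensors or response functions), curved or probabilistic streamline
geometry, measurement noise, partial-volume or extra-axonal contamination,
or realistic lesion morphology.  A green test therefore establishes the
correctness of the estimator and of the statistical machinery on an
identifiable noiseless world — not robustness to acquisition noise or
tractography errors.  Notably, on this small phantom the lesion occupies a
large share of the few WM voxels, so even the *standard* pipeline shows
group sensitivity; the real-data phenomenon that only the
multi-compartment variant detects damage needs brain-scale redundancy to
reproduce and is outside what these phantoms can certify.  On an
edgeless damaged connectome (possible at 100 % damage on the small
phantom) the cohort driver records modularity 0 rather than failing.

## Known limitations

* Dense NNLS limits problem size to phantom scale.
* Endpoint-voxel node assignment has no radial search; streamlines ending
  just outside their parcel are dropped.
* Lesion masks are built from spheres on the voxel lattice; coverage
  overshoots the target by up to one dilation increment.
* The inner permutation test assumes exchangeability of subjects across
  groups; covariate-adjusted group analyses are out of scope.
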