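# Methods

This note documents the model, the algorithmic and numerical choices, and
what the synthetic phantom does and does not establish.

## Model and assumptions

The segmentation rests on a linear mixing assumption: each voxel's
multi-parametric feature vector is a non-negative combination of a small
number of tissue-specific signatures, `X ≈ W H` with `W, H ≥ 0`
elementwise. Columns of `W` (m×r) are signatures in the 18-dimensional
feature space; rows of `H` (r×n) are spatial abundance maps. The rank is
not a free parameter: r = (number of merged pathological sources) + 8,
with two normal sources for each of white matter, grey matter, CSF and
vessels to absorb within-class variance.

The objective

    f(W, H) = ½ ( ‖X − WH‖²_F + λ ‖(L + I) H‖₁ )

adds an L1 term with two roles. `L` applies an in-plane 4-neighbour
Laplacian to each abundance map (each row of `L` is a vectorized Laplacian
kernel; adjacent slices are not coupled because the out-of-plane
resolution, 3 mm, is coarse relative to the in-plane 1 mm), so `‖LH‖₁`
penalizes roughness while tolerating sharp boundaries; the identity
component penalizes `H` directly, promoting sparse abundances. The
operator acts on each source's map, i.e. on the columns of `Hᵀ`.

Assumptions worth keeping in mind: channels must be co-registered and
resampled to one grid with the brain already extracted; pathological
tissue forms spatially coherent regions (the post-processing depends on
this); the user's seed voxels are representative of their tissue class
(seeds near compartment boundaries degrade the result — the robustness
protocol quantifies exactly this sensitivity).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| λ (regularization weight) | 0.1 | – | balance of data term and penalty on [0,1]-scaled features |
| mode | spatial_sparse | – | `no_reg`, `spatial` (`‖LH‖₁`), `spatial_sparse` (`‖(L+I)H‖₁`) |
| max_iter / rel. tolerance | 500 / 1e-6 | – | solver stopping criteria |
| merge threshold | 0.95 | cosine | seed candidates above this are averaged into one source |
| normal sources | 8 | – | 2 per normal tissue type |
| downsample factor | 2 | – | in-plane column thinning for the solve; abundances upsampled bilinearly afterwards |
| FCM fuzziness / tol / iters | 2.0 / 1e-5 / 100 | – | standard fuzzy C-means defaults |
| window sizes | 3×3 and 5×5 | voxels | in-plane neighbourhood means added as features |
| spacing | (1, 1, 3) | mm | anisotropic grid; all distances are computed in mm |

## Numerical choices

* **Non-negativity** is enforced by the substitution `W = A∘A`, `H = B∘B`
  and unconstrained optimization over (A, B); returned factors are exactly
  non-negative (squares of reals).
* **Solver.** The non-smooth `|u|` is smoothed as `√(u² + ε²)` with
  ε = 1e-9 (features live in [0, 1], so the smoothing is far below data
  scale). The search direction comes from a Gauss-Newton model — the exact
  J^T J of the residual through the squared variables plus an
  iteratively-reweighted-least-squares majorizer `Mᵀ diag(1/√(u²+ε²)) M`
  for the smoothed L1 term — solved matrix-free by Steihaug-Toint
  conjugate gradients inside a trust region (radius quartered when the
  model over-predicts, doubled when it is accurate and the step hits the
  boundary; steps accepted only when the true objective decreases, so the
  objective trace is non-increasing by construction). Convergence is
  declared when the relative change of accepted objective values falls
  below 1e-6, with `max(f, 1e-30)` guarding the denominator.
* **Scale indeterminacy.** `(W, H)` and `(cW, H/c)` fit the data equally
  well, and the one-sided L1 penalty actively drives the solver toward
  large `W` / small `H`. The factorization itself is entitled to do this,
  but a per-voxel argmax over raw abundance rows would then depend on the
  arbitrary per-source scaling. Labelling therefore ranks sources by their
  signal contribution `‖w_i‖₂ · h_ij`, which is invariant under any
  compensating per-source rescaling.
* **Laplacian boundaries.** Rows use degree-valued centres (number of
  in-plane neighbours actually present as columns), which preserves
  `L·1 = 0` on ragged voxel sets (Neumann-like boundary).
* **Duplicate normal sources.** SPA is deliberately greedy and, once the
  informative directions are deflated, its later picks are noise-driven
  and can land inside a pathological region. Frozen-centroid FCM cannot
  move such a centroid out of a compact pathological cluster (a mobile
  centroid equidistant with the frozen one always keeps half the
  membership mass), so the refined "normal" source becomes a near-copy of
  a seeded signature and would silently absorb that tissue's voxels at
  labelling time. A normal source whose cosine to a pathological source
  exceeds 0.99 therefore inherits the pathological label, and the
  per-class pooling of sources merges them. The 0.99 threshold is
  deliberately stricter than the 0.95 merge threshold because all-positive
  feature vectors are highly correlated by construction. This guard is a
  labelling decision only; the factorization is untouched.
* **NNLS initialization** solves each column independently
  (`scipy.optimize.nnls`) with memoization of repeated columns.
* **Downsampling** keeps columns at even in-plane positions; seeds are
  snapped to the nearest retained in-slice column. Upsampling interpolates
  each abundance map bilinearly in-plane after nearest-filling coarse
  cells outside the mask, so boundary voxels interpolate from valid
  values; bilinear interpolation is exact on linear fields where the
  coarse grid brackets the fine position.
* **Post-processing** uses 26-connectivity for components (permissive
  within a class) and 6-connectivity (face sharing) for the cross-class
  adjacency test — the literal reading of a "common edge". Seed-to-
  component distances are Euclidean in mm, honouring the anisotropic
  spacing; exact distance ties retain every tying component. The recovery
  pass runs once (necrosis←tumor, tumor←necrosis, edema←tumor, all against
  the step-1 masks; no fixpoint iteration), so edema adjacency to necrosis
  alone does not recover edema. Argmax ties break to the lowest source
  index; all-zero abundance columns fall to "normal" with a warning.
* **Metrics.** Hausdorff distances range over full voxel sets (not
  extracted surfaces) via Euclidean distance transforms with anisotropic
  sampling, and the robust value is the maximum of the two directed 95th
  percentiles with the linear-interpolation percentile estimator
  (pooling the two directed distance sets would be the alternative
  reading; max-of-directed is symmetric and the stricter of the two).
  Dice of two empty masks is defined as 1.0 (agreement on absence), with a
  warning. Empty masks give an infinite Hausdorff distance.
* **rCBV** integrates the K1-corrected average curve over all
  post-baseline time points (no gamma-variate fitting or bolus windowing),
  with cumulative-trapezoid integrals at the 1 s sampling. The
  non-enhancing mask defining the average curve is caller-supplied. No
  normalization to contralateral tissue is applied; the later per-feature
  [0, 1] rescaling is the only intensity calibration.
* **ADC** is fitted jointly to all b-values through a single
  mono-exponential with design `[1, −b]`, ordinary least squares for the
  initial estimate, and weights `exp(2·X·β_LLS)` for the refit; negative
  ADCs clip to 0, non-positive signals exclude the voxel with a warning.

## The phantom

The generator emulates the kind of study the method targets: a
64×64×10-voxel grid at 1×1×3 mm, an ellipsoidal brain with a cortical
grey-matter shell, ventricular CSF, two vessels and a ring-enhancing
lesion (necrotic core 6.5 mm, enhancing rim 11 mm, edema halo 16.5 mm,
optional detached necrotic satellite inside the rim). Channels are
piecewise-constant per tissue plus i.i.d. Gaussian noise (σ = 0.05 of the
intensity scale by default; Gaussian rather than Rician to keep recovery
tests analytic). The intensity table encodes the standard qualitative
contrasts (rim enhances on T1C and rCBV, necrosis and CSF are ADC-bright,
edema is FLAIR-bright) with deliberate per-channel overlap between
confusable pairs (edema/GM on T1; necrosis/CSF on T1C) so classes separate
jointly but not in any single channel. Compartment thicknesses exceed the
±2-voxel mixing width of the 5×5 averaging window so each class retains a
pure interior; with thinner compartments the factorization legitimately
spends a source on the boundary-mixture shell instead of the seeded
tissue. Matched raw series exercise the quantitative-map fits end to end:
DWI decays mono-exponentially with per-tissue ADC at b = 0/500/1000 s/mm²,
and DSC curves share a gamma-variate bolus scaled by per-tissue perfusion,
with a known leakage term injected in enhancing tumor.

What phantom results do **not** show: robustness to bias fields, motion,
registration error, partial-volume gradients, intensity non-stationarity
or anatomical variability; the piecewise-constant construction makes the
linear mixing assumption exactly true, which real tissue only
approximates. Phantom Dice values are therefore upper bounds on clinical
behaviour, and the package's validation should be read as verifying the
machinery, not predicting patient-level accuracy.

## Problem sizes

The default phantom yields ≈ 24 000 analysed voxels (≈ 6 000 after
in-plane downsampling by 2) and rank ≈ 11–12; one full pipeline run takes
roughly 10–15 s on one CPU, dominated by the 500 trust-region iterations.
The acceptance script runs five independent phantoms, a 20-run reseeding
experiment (noise σ = 0.02), a three-point λ sweep and the satellite
scenario — a few minutes in total.

## Known limitations

* The L1 penalty is scale-vulnerable: because only `H` is penalized, long
  solves drift toward large-`W`/small-`H` representations that shrink the
  effective regularization. The iteration cap bounds the drift and the
  contribution-weighted labelling is invariant to it, but reported
  objective values are not comparable across different iteration budgets.
* The duplicate-source guard uses a fixed 0.99 cosine; on real data a
  vessel source could conceivably exceed it against an enhancing-tumor
  source, mislabelling vessels as tumor. The seed-driven component
  cleanup bounds the damage to regions adjacent to the lesion.
* Sources are labelled at initialization and keep their labels; if the
  solver substantially rotates a signature (small compartments are most at
  risk), the label may no longer describe the voxels the source wins.
* The edema recovery rule checks adjacency to active tumor only, per the
  two-step design; edema touching only necrosis stays removed.
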