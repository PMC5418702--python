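# nmfseg

Semi-automated brain tumor segmentation on multi-parametric MRI using
spatially regularized non-negative matrix factorization.

High-grade gliomas are heterogeneous lesions whose compartments — enhancing
(active) tumor, necrotic core and peritumoral edema — have diffuse boundaries
on any single MRI contrast. `nmfseg` segments these compartments from a
co-registered multi-parametric study (T1, contrast-enhanced T1, FLAIR,
leakage-corrected rCBV, ADC and b0) with only a handful of user-clicked
voxels per pathological region as prior knowledge: no training data, no
atlas, no assumptions about enhancement or focality. It is aimed at
researchers in quantitative neuro-imaging who need volumetric tumor
delineations without per-protocol classifier training.

## Method

Every analysed voxel contributes one column to a non-negative matrix
`X ∈ R+^(m×n)` whose m = 18 rows are the six channel intensities rescaled to
[0, 1] plus their 3×3 and 5×5 in-plane neighbourhood means. The factorization

    min_{W≥0, H≥0}  ½ ( ‖X − WH‖²_F + λ ‖(L + I) H‖₁ )

represents each voxel as a non-negative mixture of r tissue signatures
(columns of `W`); each row of `H` is a tissue abundance map. `L` is a sparse
in-plane 4-neighbour Laplacian, so the `LH` component of the L1 penalty
promotes piecewise-smooth abundance maps with sharp tissue boundaries, while
the `IH` component promotes sparseness (λ = 0.1 by default). Non-negativity
is enforced by optimizing over square roots of the factors; the smoothed
objective is minimized with a Gauss-Newton model inside a Steihaug-CG trust
region (accepted steps never increase the objective; at most 500 iterations
or a relative change below 1e-6).

Pathological sources are initialized from the user's seed voxels
(4-neighbour-averaged feature vectors, merged when their cosine similarity
exceeds 0.95); the eight normal-tissue sources come from the successive
projection algorithm refined by fuzzy C-means with the pathological
centroids frozen; `H` is initialized by per-voxel non-negative least
squares. After the solve, each voxel takes the label of its
largest-contribution source, and a two-step connected-component cleanup
keeps the components nearest the seeds and then reinstates components
face-adjacent to retained partner tissue (necrosis↔active tumor,
edema←active tumor). Quality is scored with Dice overlap and the robust
95th-percentile Hausdorff distance for active tumor, tumor core
(active + necrosis) and whole tumor (core + edema).

Because clinical studies cannot be redistributed, the package ships a
phantom generator (`nmfseg.phantom`) that emulates such a study: an
ellipsoidal brain with grey/white matter, ventricles and vessels, a
ring-enhancing lesion (necrotic core, enhancing rim, edema halo, optional
detached necrotic satellite), per-tissue channel intensities with Gaussian
noise, matched raw DWI/DSC series, ground-truth masks and seed sets.

## Worked example

```python
from nmfseg import PhantomSpec, generate_study, NMFSegmenter, evaluate

data = generate_study(PhantomSpec(seed=0))          # synthetic glioma study
seg = NMFSegmenter(lam=0.1, mode="spatial_sparse")  # default settings
seg.fit(data.study, data.seeds)
report = evaluate(seg.result_.masks, data.truth_masks, data.study.spacing)
print(report.to_string(index=False))
```

prints

```
    grouping     dice  hausdorff95_mm
active_tumor 0.964345             0.0
  tumor_core 0.984925             0.0
 whole_tumor 0.935523             1.0
```

i.e. the pipeline recovers 96 % of the enhancing rim, 98 % of the tumor
core and 94 % of the whole lesion by Dice overlap against the phantom's
ground truth, with sub-voxel robust surface distances. `seg.nmf_` exposes
the solver diagnostics (objective trace, iteration count) and
`seg.result_.preliminary_masks` the segmentation before morphological
cleanup.

The same pipeline is scriptable from a shell:

```bash
nmfseg phantom  --out-dir ph --seed 0 --raw
nmfseg preprocess --dwi ph/dwi.nii --dwi-sidecar ph/dwi.json \
                  --dsc ph/dsc.nii --dsc-sidecar ph/dsc.json \
                  --mask ph/brain_mask.nii --nonenh-mask ph/nonenh_mask.nii \
                  --out-dir maps
nmfseg segment  --channels ph/channels.yaml --seeds ph/seeds.json --out-dir seg
nmfseg evaluate --pred-dir seg --truth-dir ph
nmfseg robustness --channels ph/channels.yaml --truth-dir ph --out-dir rob
```

Ablations (`--mode no_reg|spatial|spatial_sparse`, `--feature-mode
cmri_only`, `--no-postprocess`) compose freely through the same entry point.

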