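# trunkphenix

Non-destructive phenotyping of internal trunk tissues in woody plants from
co-registered multimodal 3D imaging.

Grapevine trunk diseases (Esca and the other dieback syndromes) silently
destroy wood from the inside: by the time foliar symptoms appear — if they
appear at all — the trunk may already hold large volumes of necrotic and
decayed tissue. The only traditional way to see that damage is to cut the
plant down. This package implements an imaging-based alternative: given
co-registered MRI (T1-weighted, T2-weighted, PD-weighted) and X-ray CT
volumes of a trunk, it classifies every voxel into five classes
(*background*, *bark*, *intact*, *degraded*, *white rot*), validates the
classifier with a leave-two-specimens-out protocol, quantifies and localizes
the tissue compartments along the trunk with geodesic distances, and grades
each vine with a threshold staging model. Because no imaging dataset of
diseased vines is publicly deposited, the package ships a seeded phantom
generator whose class-wise signal structure follows the relative inter-class
signal declines measured on real vines, so the entire workflow is exercised
end-to-end on synthetic data.

Who is it for: plant-imaging and precision-viticulture researchers who want a
reproducible reference implementation of trainable voxel segmentation plus
trunk-level diagnostics, and a sandbox for testing how such pipelines degrade
at portable-device resolutions.

## The method in brief

**Voxel classification.** For each voxel $P_i=(x,y,z)$ a feature vector
$X_i$ is built by applying a multi-scale filter bank (local mean, variance,
min, max, median, Gaussian-gradient edge magnitude, difference of Gaussians;
scales 1–64 voxels) to each modality channel. A random forest maps $X_i$ to
a class $\hat C_i$ by majority vote over trees (ties to the lower class
code).

**Validation.** With $n$ annotated specimens, all $\binom{n}{2}$
leave-two-out folds are run: train on $n-2$ specimens' annotated voxels,
score the held-out pair, sum the fold confusion matrices into a global
matrix, and report global accuracy and per-class precision/recall/F1
($F_1 = 2pr/(p+r)$). The same protocol is repeated for all $2^4-1$ modality
subsets (ablation) and for block-downsampled data (block-mean intensities,
majority labels) at voxel sizes up to 10 mm.

**Quantification and staging.** Tissue compartments are counted and placed
along the trunk by geodesic (shortest in-mask path) distance from a reference
point 20 cm below the trunk head; the signed position (distance − 200 mm) is
~0 at the trunk head. In the −2..+2 cm region around the head, the staging
model grades the vine: *critical* if intact ≤ 30% or white rot > 15%,
*low* if white rot < 8% (and intact > 30%), *moderate* otherwise.

**Phantoms.** Synthetic trunks are tortuous cylinders with a bark shell and
an axially elongated degraded lesion with a strictly nested white-rot core
near the trunk head. Class means per modality follow the measured relative
declines — intact→degraded: −19.3% (X-ray), −57.3/−86.3/−71.3% (T1w/T2w/PDw);
degraded→white rot: −56.0%, −36.8/−76.8/−64.2% — with intact normalized to
100. Twelve-vine cohorts span four foliar-symptom history categories with
lesion burden increasing with cumulative symptomatic years.

## Worked example

```python
import trunkphenix as tp

# a 4-specimen cohort of small phantoms, and per-specimen annotations
spec = tp.PhantomSpec(grid_shape=(32, 32, 48), trunk_radius=8.0, trunk_length=22.0,
                      tortuosity_amplitude=1.5, branch_radius=3.5, lesion_center_offset=5.0)
cohort = tp.generate_cohort(4, spec, seed=3)
annotations = {r.specimen_id: tp.sample_annotations(r, n_sections=10, per_class_cap=120, seed=5)
               for r in cohort}

result = tp.run_cross_validation(cohort, annotations,
                                 feature_config=tp.FeatureConfig(scales=(1,)),
                                 hyperparams=tp.Hyperparams(n_trees=25), seed=4)
print(result.report.to_frame().round(3))

r = cohort[3]   # the apoplectic vine
dmap = tp.geodesic_map(r.labels.wood_mask(), r.reference_point, r.labels.spacing,
                       reference_depth_mm=r.spec.resolved_reference_depth())
band = tp.region_fractions(r.labels, dmap, -2, 2)
call = tp.stage_vine(band)
print(call.stage, "|", call.rule)
```

Output:

```
            precision  recall     f1
background      0.996   0.999  0.997
bark            0.990   0.992  0.991
intact          0.997   0.996  0.996
degraded        0.980   0.984  0.982
white_rot       0.985   0.975  0.980
moderate | white rot 9.0% in [8%, 15%]
```

The table is the global leave-two-out confusion-matrix metrics over all six
folds: every class is recovered with F1 ≥ 0.98 under intensity noise sd 10.
The staged vine carries 9.0% white rot in the −2..+2 cm region around the
trunk head — inside the 8–15% band — so the call is *moderate*, with the
decisive rule echoed.

A CLI mirrors the library (`trunkphenix phantom | features | train | predict
| crossval | ablate | resolution | quantify | stage`), e.g.:

```bash
trunkphenix phantom --n 12 --seed 17 --out cohort/
trunkphenix crossval --cohort cohort/ --seed 7 --out results/
```

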