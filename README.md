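# podoseg

Deep-learning molecular morphometrics for kidney biopsies: segmentation
of glomeruli and podocyte nuclei from 3-channel immunofluorescence
images, annotation-free bias minimization between imaging set-ups,
model-based stereology, and per-subject morphometric signatures for
patient classification.

Podocytes are terminally differentiated glomerular epithelial cells
whose loss drives glomerulosclerosis; quantifying their number, density,
size and spacing per glomerulus ("podometrics") is a candidate
histological biomarker in immune-mediated kidney disease. `podoseg` is
aimed at image-analysis and nephrology researchers who want to run or
study that pipeline end to end. Its pieces:

* **`podoseg.unet`** — a dual-output U-Net that segments the glomerular
  area and podocyte nuclei simultaneously from (DNA, WT1, DACH1)
  channels. Training uses a balanced two-task binary cross-entropy
  `L = w_p·BCE_podo + w_g·BCE_glom` with `w_p = BCE_podo/(BCE_podo+BCE_glom)`
  (the currently poorer task gets more weight), ε-clipped predictions
  (ε = 1e-7), border-emphasizing weight maps
  `w(x) = w_c(x) + w0·exp(−(d1+d2)²/2σ²)` on the nuclei task,
  flip/shift/rotation augmentation, subject-grouped 60/20/20 splits,
  RMSprop, and best-validation-Dice checkpointing.
* **`podoseg.gan`** — a U-Net cycleGAN (encoder / 9 ResNet blocks /
  decoder with skip concatenations; 6-layer patch discriminator;
  least-squares adversarial + cycle (λ=10) + identity (λ=5) losses) that
  transforms images from a shifted microscope/operator domain into the
  reference appearance, with Gaussian/Laplacian pyramids carrying
  full-resolution detail through the 256 px working size.
* **`podoseg.stereology`** — per-glomerulus 3-D podometrics from one
  2-D section: glomerular volume `V = (β/k)·A^{3/2}`, sphere-model
  nuclear caliper diameter, thickness-corrected podocyte number
  `N = n/(A·(d+t))·V`, density per 10⁶ µm³, and closest-neighbor
  distances.
* **`podoseg.signature`** — the 25-feature subject signature
  ({min, max, mean, median, variance} × {number, density, distance,
  nuclear area, glomerular area}), leave-one-out logistic
  classification with fold-local z-scaling, Pareto-scaled PCA of single
  glomeruli, and the clinical-score / podocyte-size-range ratio.
* **`podoseg.synthetic`** — a seeded generator of 3-D glomerular scenes
  (spherical tuft, non-overlapping spherical nuclei, podocyte-specific
  channel signatures, focal lesions, microscope shifts) rendered into
  images plus exact ground-truth masks, so the whole pipeline is
  testable without patient data.
* **`podoseg.nn`** — a compact numpy reverse-mode autodiff engine
  (channels-last convolutions as per-tap BLAS matmuls) that the two
  networks run on; every operation is gradient-checked in the tests.

## Worked example

Simulate a two-group cohort, compute podometrics from the ground-truth
masks, and classify subjects by their morphometric signature:

```python
from podoseg.synthetic import CohortSpec, SceneParams, simulate_cohort
from podoseg.stereology import (StereologyParams, glomerulus_podometrics,
                                records_to_frame)
from podoseg.signature import signature_frame, loo_classify

spec = CohortSpec(n_subjects_per_group=10, glomeruli_per_subject=(5, 7),
                  scene=SceneParams(glom_radius_mean_um=45,
                                    glom_radius_sd_um=4,
                                    podocyte_count_mean=55,
                                    podocyte_count_sd=10),
                  image_size=128, seed=7)
samples, truth = simulate_cohort(spec, images=False)

params = StereologyParams.for_equatorial_sections()
records = [glomerulus_podometrics(s.masks, params, s.subject_id,
                                  s.glomerulus_id, s.lesion)
           for s in samples]
glom = records_to_frame(records)
print(glom[["subject_id", "n_podocyte_profiles", "podocyte_number_est",
            "podocyte_density_per_1e6um3"]].head(3).round(1))

meta = truth[["subject_id", "group"]].drop_duplicates()
result = loo_classify(signature_frame(glom, meta))
print(f"LOO AUC {result.auc_roc:.3f}  accuracy {result.accuracy:.2f}")
```

prints

```
  subject_id  n_podocyte_profiles  podocyte_number_est  podocyte_density_per_1e6um3
0       c000                    8                 60.3                        119.0
1       c000                   11                 86.4                        190.8
2       c000                    7                 52.6                        145.9
LOO AUC 1.000  accuracy 1.00
```

Each row is one glomerulus: 8 nuclear profiles were counted in the
section of `c000_g00`, and the thickness-corrected stereological
estimate extrapolates them to ≈60 podocytes in the whole glomerulus
(the generator's true 3-D count for that glomerulus is 64). With the
default disease effect — podocyte count ×0.6, nuclear area ×1.3, 30%
focally depleted glomeruli — the 25-feature signature separates the two
groups of 10 subjects perfectly under leave-one-out evaluation.

The same chain is available from the shell:

```
podoseg simulate --out cohort --seed 7
podoseg train-seg --manifest cohort/manifest.csv --out run --seed 7
podoseg segment --model run/segmenter --manifest cohort/manifest.csv --out masks
podoseg evaluate --pred masks --manifest cohort/manifest.csv --out report.json
podoseg podometrics --manifest cohort/manifest.csv --masks masks --out glom.csv --equatorial
podoseg classify --glom glom.csv --meta subjects.csv --out results/
```

(`podoseg run-all --out run --seed 7` chains everything at desk scale;
`podoseg train-gan` / `transfer` handle the bias-minimization models.)

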