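# babytract

Infant white-matter tractometry and quantitative-MRI development modelling.

`babytract` is for researchers studying early postnatal white-matter
maturation with diffusion and quantitative MRI. It re-implements, as a
tested Python toolkit, the analysis chain needed to ask *where and how fast
the infant brain myelinates*:

1. **Bundle segmentation** — classify a whole-brain tractogram into 24
   named bundles (11 per hemisphere plus forceps major/minor) using
   ordered waypoint ROIs defined on an infant template: a streamline is a
   candidate for a bundle only if it passes through all of the bundle's
   waypoints in order; multi-bundle candidates are resolved with a
   probabilistic atlas; bundles are cleaned by removing streamlines more
   than 4 SD of Mahalanobis ("gaussian") distance from the bundle core.
   Dice-coefficient utilities (DC = 2|A∩B| / (|A|+|B|)) support validation
   against reference segmentations.
2. **Tract profiling** — resample each bundle to 100 equidistant nodes and
   evaluate a scalar map (R1 [s⁻¹] or mean diffusivity [mm²/s]) at each
   node, with validity-aware trilinear sampling so that a ventricle
   exclusion mask blocks CSF partial-volume contamination.
3. **Relaxometry** — voxel-wise T1 (and R1 = 1/T1) estimation from
   inversion-recovery magnitude series by fitting |S(t)| = |a(1 − b
   e^(−t/T1))| with multi-start nonlinear least squares.
4. **Development models** — staged linear mixed models (LMMs):
   per-bundle and per-node `value ~ 1 + age + (1|subject)` give development
   rates; rates are then modelled over every 10th node as

   * model 1 (speed-up): `slope ~ 1 + newborn + (1|bundle)`
   * model 2 (spatial):  `slope ~ 1 + |x| + y + z + |x|·y + |x|·z + y·z + (1|bundle)`
   * model 3 (combined): union of both,

   with z-scored coordinates, REML estimates, and a likelihood-ratio test
   of model 3 against model 2.
5. **Synthetic phantom** — a fully seeded longitudinal cohort (streamlines,
   waypoint atlas, R1/MD volumes, IR series, ventricle analog) generated
   from known coefficients of the same model family, so every stage of the
   pipeline can be validated against exact ground truth.

## Worked example

Run the complete phantom pipeline from the shell:

```bash
babytract run-all --seed 7 --out demo/
```

which generates the default cohort (24 bundles, 29 sessions across
newborn / 3-month / 6-month timepoints), segments, profiles and fits all
models. `demo/models.json` then contains, e.g.:

```
mean_bundle  : 24 per-bundle development rates, e.g. CS_L slope 5.41e-04 /day
model2_spatial beta: zz 1.75e-04, zy -1.07e-04, zy_zz 1.08e-04
model3_combined beta: newborn_mean -3.0e-03
lrt_3_vs_2   : p = 2.1e-126
```

Reading these numbers: averaged over the 24 bundles, `slope × 180 ≈
0.16 s⁻¹` of R1 gain over the first six months (individual bundles differ —
the corticospinal tract starts with the highest R1 and therefore develops
slowly under the speed-up effect); the positive `zz` and negative `zy`
coefficients say development accelerates inferior→superior and
anterior→posterior; the negative `newborn_mean` coefficient is the
speed-up effect — tissue that starts with lower R1 (less myelin) gains R1
faster. The same stages are available as library calls
(`segment_all`, `compute_profile`, `TractLMM(...).fit()`,
`fit_slope_models`) returning Model/Results objects with `summary()`.

The equivalent in-memory session:

```python
from babytract.phantom import PhantomConfig, generate_phantom
from babytract.segmentation import segment_all
from babytract.pipeline import profile_phantom_sessions, grand_mean_by_timepoint
from babytract.models import fit_mean_bundle_development

data = generate_phantom(PhantomConfig(seed=7, make_md=False))
bundles = segment_all(data.streamlines, data.atlas)
table = profile_phantom_sessions(data, bundles, "r1")
print(grand_mean_by_timepoint(table, "r1"))
#  0m 0.4608   3m 0.5440   6m 0.6252
dev = fit_mean_bundle_development(table, "r1")
print(dev["slope"].mean() * 180)   # 0.1600
```

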