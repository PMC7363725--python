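# oralsurf

Quantification of intra-oral surface areas from CBCT-style voxel volumes,
with synthetic phantoms providing exact analytic ground truth for every
pipeline stage.

The pipeline: Hounsfield-unit threshold segmentation (soft tissue at
−300 HU, bone at 350 HU) with Gaussian pre-smoothing and morphological
closing → marching-cubes isosurface meshing with STL import/export and
flat hole filling → landmark-driven partition of the surface into four
regions (hard palate, tongue, hard tissue = crowns/alveoli, remaining
mucosa) → per-region areas in cm². Companion modules compute twelve
craniofacial landmark distances and the reliability statistics that tie
repeated measurements together: two-way absolute-agreement ICC (average
and single measures), Pearson correlation with a t-based test, one-way
ANOVA from raw vectors or per-group (mean, sd, n) summaries, and a
publication-style group report (mean ± SD per group, ANOVA p, ICC,
median ICC, soft-tissue subtotal).

## Modules

| module | purpose |
| --- | --- |
| `oralsurf.phantom` | voxel phantoms from analytic primitives (sphere, dome, ellipsoid, cylinder, box) with exact truth areas, air bubbles, HU noise; synthetic rater tables and correlated pairs |
| `oralsurf.segmentation` | `HUVolume`/`BinaryMask`, thresholding, Gaussian smoothing, ball-element closing, the two-threshold pipeline |
| `oralsurf.meshing` | marching-cubes extraction, triangle areas (mm² internally, cm² reported), boundary-loop flat filling, binary/ASCII STL |
| `oralsurf.partition` | `PartitionRules` (occlusal/lip planes, hamuli, ridge curves, tooth seeds), face labeling, per-region area reports, end-to-end `run_pipeline` |
| `oralsurf.anthropometry` | named 3-D landmarks, the twelve distance measures, palatal width with ridge-estimate fallback, repeat-measurement tables |
| `oralsurf.stats` | ICC(A,k)/ICC(A,1), interpretation scales, Pearson + `p_from_r`, one-way ANOVA, group aggregation |

## CLI

```sh
oralsurf phantom --scale 1.0 --spacing 0.3 --seed 1 --out phantom/
oralsurf segment --vol phantom/volume.raw --soft-hu -300 --bone-hu 350 --out masks/
oralsurf mesh    --mask masks/soft.raw --fill-max 80 --out surface.stl
oralsurf run     --vol phantom/volume.raw --rules phantom/rules.json --out report/
oralsurf anthro  --landmarks phantom/landmarks.json --out anthro.csv
oralsurf stats icc --table table.csv
```

Volumes and masks are stored as raw arrays with a JSON sidecar (shape,
dtype, spacing, origin); landmarks and partition rules are JSON; meshes
are STL.

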