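# assembloid-quant

Boundary-referenced quantification of tumor-cell infiltration in neural
assembloids — fused organoid models in which eGFP-labeled diffuse midline
glioma (DIPG) cells invade cortical organoid tissue. The package measures
how deep labeled cells travel past the fusion boundary, compares
infiltration and marker readouts between genetic or pharmacological arms
(e.g. integrin knockdowns, radiotherapy), and scores companion migration
and dose-response assays.

## What it does

The analysis follows the imaging workflow used for assembloid cryosections:

1. **Image and ROI I/O** (`io`) — OME-TIFF stacks with channel names and
   physical pixel size; fusion-boundary polygons as ImageJ `.roi` or JSON;
   CSV/YAML experiment manifests (group x treatment x replicate).
2. **Boundary geometry** (`geometry`) — maximum z-projection, exact
   point-in-polygon tests, exact minimum Euclidean distance from each
   interior pixel to the traced boundary (no grid distance transform), and
   partition of the interior into equal-width concentric shells (absolute
   µm or percent of maximum depth).
3. **Infiltration quantification** (`infiltration`) — per-shell
   mean(eGFP)/mean(DAPI) profiles, total infiltration past a depth
   threshold, exponential decay-length estimation from threshold curves,
   whole-image / interior / interface-band marker ratios (CC3, γH2AX)
   with within-group normalization to the untreated arm, and per-cell
   H3K27M infiltration distances.
4. **Migration assay** (`migration`) — spheroid spread area at 0 h vs
   24 h by Otsu segmentation; the ratio is the migration metric.
5. **Response statistics** (`stats`) — one-way ANOVA, Dunnett and Tukey
   multiple-comparison families, two-way ANOVA, relative viability, and
   weighted four-parameter-logistic IC50 fits, with the usual
   significance-star tiers.
6. **Synthetic scenes** (`synthetic`) — a seeded generator producing
   assembloid images with known boundary, cell depths (exponential law),
   marker effects, migration disks, and dose tables, used to validate
   every stage against ground truth.

## Worked example

Generate one synthetic assembloid scene (a 420 × 420 px cryosection at
1 µm/px, 400 infiltrating cells with a 50 µm depth-decay scale), project
it, and quantify infiltration relative to the traced boundary:

```python
from assembloid_quant import (
    SceneParams, generate_assembloid_scene, max_project,
    interior_distance_field, bin_shells, shell_profile,
    infiltration_metric, total_infiltration, fit_decay_length,
)

stack, roi, truth = generate_assembloid_scene(SceneParams(seed=7))
proj = max_project(stack)
fld = interior_distance_field(roi, proj.shape, proj.pixel_size_um)

print(fld.max_depth_um)            # 175.22 µm, 102,202 interior pixels
profile = shell_profile(proj, bin_shells(fld, 5), ["eGFP", "DAPI"])
print(infiltration_metric(profile))
# shell
# 0    1.0607     <- boundary shell: densest tumor signal
# 1    0.8015
# 2    0.7316
# 3    0.6755
# 4    0.7666     <- deep core
print(total_infiltration(proj, fld))   # 0.8812
print(fit_decay_length(proj, fld))     # 48.78 µm (true value 50)
```

Compare knockdown arms against the non-targeting control with Dunnett's
test:

```python
import numpy as np
from assembloid_quant import dunnett

rng = np.random.default_rng(0)
groups = {"NT":       rng.normal(1.00, 0.08, 5),
          "ITGA6_KD": rng.normal(0.62, 0.08, 5),
          "ITGB4_KD": rng.normal(0.55, 0.08, 5)}
fam = dunnett(groups, "NT")
print(fam.comparisons[["contrast", "estimate", "t", "p_adj", "stars"]])
#      contrast  estimate     t    p_adj stars
# ITGA6_KD - NT    -0.373 -8.49 2.04e-06  ****
# ITGB4_KD - NT    -0.523 -11.9 5.27e-08  ****
```

Fit an IC50 from a noisy viability plate (constant-CV noise; the fit
weights residuals accordingly):

```python
from assembloid_quant import generate_dose_response, fit_4pl

df, truth = generate_dose_response(3.1, hill=1.0, bottom=0.05,
                                   cv=0.05, seed=11, replicates=8)
fit = fit_4pl(df["dose"].values, df["viability"].values)
print(fit.ic50, fit.hill)   # 2.885 nM (true 3.1), hill 0.980
```

The same workflows are available from the command line:

```bash
assembloid-quant simulate --kind groups --out demo --seed 3 --n-images 2
assembloid-quant quantify --manifest demo/manifest.csv \
    --what infiltration --shells 5 --out shells.csv
assembloid-quant stats --data values.csv --design one_way \
    --method dunnett --control NT --out dunnett.json
```

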