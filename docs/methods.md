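# Methods

This note documents the models, parameter choices, and numerical methods
behind `assembloid-quant`. The package quantifies tumor-cell infiltration
in fused organoid ("assembloid") models of diffuse midline glioma, where
eGFP-labeled tumor cells invade cortical organoid tissue across a traced
fusion boundary, plus the companion migration, marker, and viability
readouts used to compare experimental arms.

## 1. Boundary geometry

**Projection.** Multi-z stacks are reduced by maximum-intensity
projection per channel. Infiltration readouts are 2-D measurements on
cryosection-style images; the maximum projection matches how such
sections are scored visually and is robust to focus variation between
z-planes.

**Point-in-polygon.** Containment uses the even-odd (ray-parity) rule,
vectorized over pixels per boundary segment. Points lying on an edge
(within 1e-9) count as interior, so traced cells sitting exactly on the
boundary are never silently dropped. For simple polygons even-odd and
winding-number rules agree; the test suite verifies 100% agreement with
Shapely's predicate away from a 1e-12 edge band.

**Distance to boundary.** Each interior pixel center's depth is the exact
minimum Euclidean distance over all boundary segments (projection onto
each segment, clamped to its endpoints), scaled by the physical pixel
size. We deliberately avoid grid distance transforms (e.g. EDT of a
rasterized mask): rasterization quantizes the boundary to pixel corners
and biases distances by up to half a pixel, while the exact computation
is O(pixels x vertices) — at most a few hundred ms for a 420² image and
a 64-vertex boundary — and is verified against Shapely to 1e-9.

**Shells.** The interior is partitioned into equal-width concentric
shells either in absolute µm or in percent of the image's maximum depth
(useful when assembloid sizes differ). Bin edges are half-open with the
last bin closed, so the deepest pixel is always labeled and shell counts
sum exactly to the interior count. Empty shells are flagged, not
silently averaged.

## 2. Infiltration metrics

**Per-shell profile.** For each shell, the metric is
mean(eGFP)/mean(DAPI) over the same pixel set — a ratio of means, not a
mean of per-pixel ratios, which is robust to pixels with zero DAPI.
Shells with zero nuclear signal yield NaN (never 0 or infinity).

**Total infiltration.** mean(eGFP)/mean(DAPI) over all interior pixels
deeper than a threshold (absolute µm or fraction of maximum depth;
threshold 0 covers the whole interior). Ratio metrics are invariant to
joint channel rescaling and linear in numerator-only rescaling, which the
acceptance suite checks to 1e-12.

**Decay length.** Infiltrating cell depth is modeled as exponential with
scale λ (the generator's is exactly that law). For the threshold curve
s(T) = Σ eGFP over pixels deeper than T, the model is

  s(T) = a·(e^(−T/λ) − e^(−D/λ)) + b·count(T),

where D is the maximum depth (the truncation constant: no cells exist
deeper than the inradius) and b·count(T) absorbs constant background in
the tumor channel. Estimation is a 1-D profile search: for each λ on a
120-point geometric grid the optimal (a, b) come from non-negative least
squares, and the best λ is refined by bounded scalar minimization. The
threshold grid spans 0 to 0.9·D in 19 steps so the pure-background tail
anchors b — with short grids, background and signal are nearly collinear
and the fit is unidentifiable. Pooling across scenes uses one shared
grid; 20 default scenes recover λ = 50 µm within 10% (acceptance A5).

**Marker ratios.** Σ marker / Σ DAPI over a region: whole image,
interior, or an interface band (interior pixels within a chosen depth of
the boundary, emulating fields of view at the fusion interface; width is
a parameter, default 200 µm). Optional background subtraction removes a
constant per-pixel offset before summing — `"median"` uses each
channel's image median, a robust offset estimate when most pixels are
unstained. Raw sums (the default) mirror common practice but note that a
nonzero camera offset attenuates between-group ratio differences toward
1; with median subtraction the generator's 2.5-fold marker effect is
recovered as 2.52.

**Normalization.** Treated/untreated comparisons divide each image's
ratio by the mean ratio of the *same group's* untreated images, so every
group's untreated mean is exactly 1 and normalization never crosses
groups (acceptance A12).

**Per-cell distances.** H3K27M+ cells are detected by global Otsu
threshold → connected components (≥ 4 px) → intensity-weighted
centroids; interior centroids get their exact boundary distance,
exterior ones are counted but excluded. On synthetic scenes with known
cell positions the distance RMSE is ≈ 0.05 px (acceptance A11 bound:
1 px).

## 3. Migration assay

Spread area at each time point: Otsu threshold (or a numeric threshold)
→ largest connected component → binary hole filling (dense spheroid
cores image darker) → pixel count. The metric is area(24 h)/area(0 h).
Identical frames give exactly 1.0; synthetic disks with doubled radius
give 4.0 within 2% across noise seeds (acceptance A10).

## 4. Response statistics

**One-way ANOVA** from explicit sums of squares; for two groups F equals
the pooled t² to 1e-10 (acceptance A8).

**Dunnett's test** (arms vs control): per-comparison t statistics on the
pooled error variance; the familywise adjustment evaluates the joint
multivariate-t box probability with the standard equicorrelated
structure ρᵢⱼ = λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), via seeded quasi-Monte Carlo
(`scipy.stats.multivariate_t.cdf`), accurate well below 1e-3. With one
comparison it reduces exactly to the pooled t-test. `scipy.stats.dunnett`
serves as the independent test oracle.

**Tukey's HSD** uses the studentized-range distribution with the
Tukey-Kramer standard error for unbalanced groups;
`statsmodels.pairwise_tukeyhsd` is the oracle. Both families keep
adjusted p ≥ unadjusted p, and both hold familywise error within
[0.03, 0.07] at nominal 0.05 over 2,000 Gaussian-null replicates
(acceptance A7).

**Two-way ANOVA** (group × treatment) uses an OLS fit with type-II sums
of squares via statsmodels, with empty design cells rejected by name and
Tukey comparisons on one factor's marginal means using the residual MSE.

**Significance tiers** follow the figure-legend convention with strict
inequalities (\*p < 0.05, \*\*p < 0.01, \*\*\*p < 0.001,
\*\*\*\*p < 0.0001); boundary values fall in the weaker tier.

**4PL dose-response.** r(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill),
fit on log10 dose by multi-start least squares (inflection starts at
five quantiles of the dosed range × two hill starts) with bounds keeping
log10 IC50 within the dosed range ± 3 decades. Residuals are divided by
the model value by default — the maximum-likelihood weighting for
plate-reader noise with constant coefficient of variation — with the
divisor floored at 5% of the response range so a zero bottom plateau
cannot dominate the loss. Unweighted fitting is available
(`weighting="none"`); under constant-CV noise it has visibly larger IC50
sampling error (a regression test asserts the ordering). Diagnostics:
constant responses yield a flat fit with no IC50; an IC50 outside the
dosed range triggers a "doses do not span the transition" warning.
Standard errors come from the Jacobian pseudo-inverse at the optimum.

The A9 calibration experiment uses 8 replicates per dose: at cv = 5%
that is the sample size at which the IC50 sampling SD drops to ~5% of
truth, making "within ±10% in ≥ 95% of fits" attainable (measured
97%). Eight technical replicates per dose is a routine 96-well design.

## 5. Synthetic scene generator

Scenes are the package's validation substrate; all defaults describe a
40-µm assembloid cryosection imaged at 10X (1 µm/px, 420² px, two
z-planes).

- **Boundary**: a jittered ellipse (recipe string
  `ellipse(cx, cy, rx, ry, n_vertices, jitter)`), validated as a simple
  polygon. Default: ~180 µm radius, 64 vertices, 3% radial jitter.
- **Tumor cells** (default 400): depth from the boundary is drawn from
  Exp(λ = 50 µm) and realized *exactly* by placing the cell uniformly
  along the inward-offset contour at that depth (the boundary of the
  polygon eroded by d). Depths beyond the inradius are redrawn, so the
  realized law is the exponential truncated at the maximum depth — the
  recorded ground truth passes a KS test against that law. Naive
  approaches (stepping inward along edge normals) bias realized depths
  by tens of percent on jittered boundaries; the offset-contour
  construction avoids this.
- **Nuclei**: a Poisson number at 0.008 nuclei/µm² of interior area,
  uniform inside the boundary; tumor cells also carry a nucleus.
- **Rendering**: Gaussian blobs (σ = radius/2, truncated at 4σ); channel
  gains DAPI 120, eGFP 150, markers 100. Nuclear markers (CC3, γH2AX,
  Ki67) render on all nuclei, tumor markers (H3K27M) on tumor cells
  only, with per-group effect multipliers.
- **Noise**: Poisson-Gaussian camera model — variance ≈
  poisson_scale·signal + sd², defaults (1.0, 2.0) plus a constant
  background offset of 5, clipped at 0; each z-plane gets independent
  noise.
- **Determinism**: every record's seed derives from
  `np.random.SeedSequence([base, group_index, replicate])`, masked below
  2³¹.

**Realism and limits.** The generator reproduces the features the
estimators rely on (boundary-referenced depth law, two-channel
normalization, proportional camera noise, marker multipliers) but not
tissue texture, anisotropic invasion routes, out-of-plane cell loss, or
optical effects (vignetting, depth-dependent attenuation). Group effects
are implemented as a reduced number of infiltrating cells
(`infiltration_effect` scales n_cells); reduced depth scale is available
by setting `decay_length_um` per group. Conclusions about estimator
accuracy therefore transfer to real images only to the extent these
simplifications hold; the geometry and statistics layers are
generator-independent and are verified against exact oracles instead.

## 6. Problem sizes and budgets

Defaults were chosen so the full test suite (unit + acceptance) runs in
about 10 minutes on one CPU: 420² scenes cost ~0.6 s to generate and
~0.4 s for a distance field; a 160² "small scene" pipeline step costs
~0.1 s, making 100-experiment power studies (~2,000 scenes) feasible;
one Dunnett family costs ~4 ms per multivariate-t evaluation, so
2,000-replicate null calibrations finish in minutes.
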