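# Methods

## Image model and stain separation

Brightfield IHC transmission follows Beer–Lambert: for incident intensity
`I0` (default 255) and per-channel optical density `OD`, the camera sees
`I = I0 · 10^(−OD)`. Stain contributions add linearly in OD, so a pixel's OD
vector is `c · M`, where `M` stacks three unit absorption vectors
(hematoxylin `[0.650, 0.704, 0.286]`, DAB `[0.269, 0.568, 0.778]` — standard
published values — and a residual row). The residual row completes the basis;
the orthogonal complement of H and DAB has a negative green component, so it
is clipped to zero and renormalized, keeping all rows non-negative while the
matrix stays well-conditioned (condition number checked at construction,
error above 1e6). Unmixing solves the 3×3 system per pixel and clips negative
amounts to zero. The log transform guards zeros with `ε = 1` on the 0–255
scale; this biases recovered OD downward by at most ~0.03 at the darkest
intensities the generator produces, well inside the classification margins
below.

## Intensity classes

DAB amounts are binned on the deconvolved-DAB axis (the axis on which
pixel-densitometry intensity classes are best defined; raw RGB brightness
mixes in the counterstain) with half-open intervals and boundary values
promoting to the higher class: negative `[0, 0.15)`, weak `[0.15, 0.45)`,
moderate `[0.45, 0.85)`, strong `[0.85, ∞)`. The cutpoints are configuration,
not constants of nature: they are placed midway between the generator's
deposit levels (weak 0.30, moderate 0.65, strong 1.10) so that noise-free
renders are recovered essentially perfectly after 8-bit quantization; real
scanners/stains need recalibration, which is why `IntensityThresholds` is an
explicit config object.

The pixel H-score is `100·(1·f_weak + 2·f_moderate + 3·f_strong)` over
tissue-pixel fractions, range 0–300. It is computed over pixels, not cells,
because no per-cell intensity assignment exists in a pixel-densitometry
pipeline.

## Tissue, nuclei, zones

Tissue is detected as total OD above a floor (default 0.05), morphologically
closed, hole-filled, largest component kept; %SA denominators use this mask
(area = pixel count × (µm/px / 1000)²). Nuclei are segmented from the
hematoxylin channel (threshold 0.3) with a distance-transform watershed and
physical area bounds (5–400 µm²).

Zoning uses one Euclidean distance field `d(p)` from the nuclei, in µm:
intracellular/cell regions at `d ≤ 3` (cytoplasm modelled as a fixed rim —
no membrane stain is available), capsular band `3 < d ≤ 5`, paracapsular band
`5 < d ≤ 8`, interterritorial beyond. All widths are `ZoneParams`
configuration; the source material gives no band widths ("two tiny sites"),
so these defaults were fixed once and pinned by the synthetic recovery tests.
Defining both bands as shells of the *same* distance field matters
numerically: chaining a second distance transform off the rasterized cell
mask loses ~¼ pixel of band width per step (the transform measures to pixel
centers, not the region boundary), which is a 5–10% area error for 2–3 µm
bands at 0.5 µm/px; single-field shells cancel the rasterization offset and
match analytic annulus areas to well under 2% at test resolution. Cell
regions closer than `nest_gap` (default 5 µm, implemented as morphological
closing with a disk of half that diameter) merge into nests; matrix enclosed
by a nest is reassigned to the cell compartment, while open matrix keeps its
shell label by distance-to-nearest-cell. Closing is idempotent, so nest
merging is too.

Territorial %SA counts *any* positive class inside
intracellular∪capsular∪paracapsular; interterritorial %SA the same over the
remaining tissue. Location and intensity stay independent measurement axes —
the strong↔territorial association is an empirical property of specimens
(and of the generator's defaults), not part of the definition. Because the
zones partition tissue, territorial + interterritorial %SA equals total
positive %SA exactly.

## Synthetic cores

The generator is a forward model, not a photorealistic simulator. A tissue
disc (radius 0.47 × image size) carries a faint hematoxylin tint (0.06) so
tissue detection has signal; nuclei (default 100, radius 4 ± 0.5 µm) are
placed by a Poisson-cluster process (~8 nuclei per cluster, cluster sd
12 µm) with a 9 µm minimum center separation — an explicit `GeometryError`
is raised if the requested count cannot be placed, never a silent
truncation. Default geometry is a 512 px square at 0.5 µm/px: a scaled-down
cylinder (256 µm field rather than 1 mm) that keeps the 2–3 µm bands several
pixels wide; nuclei density in this packed field (~2200/mm²) is higher than
typical whole-cylinder medians (~560–1100/mm²), which is irrelevant to the
recovery questions the generator serves.

DAB is deposited on pixels sampled from a pattern-specific candidate pool:
territorial → the true territorial zone, interterritorial → the true
interterritorial zone, mixed → all tissue, none → nothing. Requesting a
positive fraction larger than the pool raises `GeometryError` (an all-tissue
target like fraction 1.0 uses the mixed pattern). Class labels are drawn
from `class_mix`, renormalized over positive pixels (the weights only define
proportions; every positive pixel needs a class). Default mixes encode the
observed intensity–location association: territorial deposits skew strong
(0.1/0.2/0.7), interterritorial weak-to-moderate (0.6/0.4/0). Optional
Gaussian noise is added in OD space (default sd 0.01; recovery and
calibration tests use 0 to isolate algorithmic error from noise). Ground
truth (%SA, H-score, density) is computed by direct pixel counting on the
true maps, using the same `ZoneParams` as the analysis defaults.

What the generator does **not** emulate: chromatic scanner variation,
uneven illumination, tissue folds/tears, out-of-focus blur, nucleus texture
and ellipticity, stromal structures, stain co-localization gradients.
Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated image model, not robustness to real-slide
artifacts.

## Synthetic cohorts

Cases carry independent Bernoulli covariates at plausible frequencies for a
mixed neuroblastoma cohort (age ≥ 18 mo 0.55, metastatic stage 0.45,
unfavorable histology 0.60, MYCN amplification 0.20, segmental profile 0.45,
11q deletion 0.25, high risk 0.40, high instability 0.40). Morphometric
metrics are lognormal with medians loosely matched to reported tumor values
(territorial %SA median 0.71 with a heavy right tail, interterritorial 9.35,
H-score 110, density 560/mm²) and an upward shift for high-risk cases on the
staining metrics; these are plausibility settings, not calibrated claims —
no per-stratum distributions are published. Two cylinders per case are drawn
around the case mean (log-sd 0.05) and averaged, mirroring the
mean-of-cylinders convention.

Survival is exponential with log-linear effects:
`λ_i = λ0 · hr_terr^{1[terr_i ≥ Q3]} · Π_k hr_k^{x_ik}` with default hazard
ratios mirroring the magnitudes reported for such cohorts (age 3.9,
histology 2.9, 11q 2.4, MYCN 2.36, territorial indicator 2.34; λ0 = 0.05/yr
for EFS, OS at 0.6×, with OS time floored at the EFS time). The exponential
form is the simplest model satisfying proportional hazards, so Cox recovery
has a known truth. Censoring: `censoring_rate = 0` disables censoring
entirely (every case is an event); otherwise censoring times are exponential
at the rate giving the requested baseline censoring share, capped at the
follow-up horizon (default 10 y). Under all-unit hazard ratios the pooled
Kaplan–Meier curve converges to `exp(−λ0 t)` (tested at n = 2000, sup
distance ≤ 0.03).

## Statistics

- **Q3 dichotomization**: third quartile by the linear-interpolation
  (type-7) quantile; ties at the threshold go to the high group (≥ Q3);
  an all-equal input produces a flagged degenerate all-high split.
- **Rank tests**: Mann–Whitney U from midranks with the tie-corrected normal
  approximation, two-sided, no continuity correction; Kruskal–Wallis H with
  tie correction and a χ² p on k−1 df. Without a continuity correction the
  two-group Kruskal–Wallis p equals the Mann–Whitney p (χ²(1) of z²), which
  the tests exploit as a cross-check; scipy implementations serve as an
  independent reference, never the code path.
- **Kaplan–Meier / log-rank**: delegated to lifelines; events precede
  censorings at tied times; 5-year rates are read off the step function.
  Hand-tabulated product-limit and O−E/variance oracles verify both.
- **Cox**: lifelines partial likelihood with Efron tie handling (the only
  handling lifelines implements; preferred for discrete ties anyway).
  Backward Wald elimination removes the covariate with the largest Wald
  p-value above `alpha_stay` (default 0.1, matching the reporting band such
  studies use for retained terms) and refits until all survivors pass; the
  elimination trace is reported. Exp(B) = exp(B) and CI = exp(B ± 1.96·SE)
  by construction. Non-convergence raises an explicit error.
- Significance is 0.05 throughout the reporting tables.

The cohort pipeline excludes cases with territorial + interterritorial
%SA = 0 ("no immunoreactivity") before testing, sorts by case id so results
are row-order invariant, and enters into each Cox model the INRG-style
factors plus Q3 indicators of the metrics whose log-rank test was
significant for that endpoint.

## Numerical and degenerate-input conventions

Pixel grid is 0-based with area = pixel count × pixel area; no sub-pixel
geometry. Empty tissue, empty groups, absent events, non-finite fields and
invalid thresholds raise typed errors with the failing stage prefixed in
pipeline runs; an empty nuclei set downgrades to a warning (whole tissue
interterritorial). All randomness flows through `numpy.random.default_rng`
seeds carried in the spec/params objects, so images, cohorts, metric tables
and reports are bit-reproducible under a fixed seed and config; the run
manifest echoes every parameter plus a SHA-256 config hash.

## Problem sizes used in validation

Recovery suites use 20 cores at 512² px; calibration uses 1000 null
cohort replicates at n = 200 for log-rank type-I error and a single n = 500
cohort for Cox hazard-ratio recovery; oracle equivalence runs on ≤ 64×64
maps and n ≤ 20 toy vectors where brute force is exact. These sizes were
chosen as the smallest at which the targeted properties are informative.

## Known limitations

- Band widths, stain vectors and thresholds are surrogates for unpublished
  vendor-tool settings; absolute metric values on real slides depend on
  recalibrating them.
- Cell regions are nucleus dilations; true cytoplasmic extent varies, so
  "intracellular" conflates nucleus and near-cytoplasm.
- The cohort simulator's covariates are independent; real prognostic factors
  are correlated, so multivariable elimination behavior on real data can
  differ.
- No competing risks, time-varying covariates or multiple-testing
  correction.
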