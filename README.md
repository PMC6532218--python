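# ihczone

Zonal quantification of DAB immunohistochemistry in tissue-microarray (TMA)
cores, with the cohort-level survival statistics used in biomarker studies.

The package targets a common question in tumor-microenvironment pathology:
given brightfield images of immunostained cores (hematoxylin counterstain +
brown DAB chromogen, e.g. against an extracellular-matrix protein such as
vitronectin in neuroblastoma), how much staining is there, how intense is it,
and — crucially — **where** is it relative to the cells? Staining inside
cells and in the thin pericellular bands that wrap single cells or nests of
grouped cells (a *capsular* rim plus a *paracapsular* layer) is called
**territorial**; staining in the matrix beyond those bands is
**interterritorial**. The per-case measurements are then tested as prognostic
biomarkers against survival endpoints.

## What it computes

Per cylinder image:

- Beer–Lambert optical densities, `OD = -log10((I + ε)/I0)`, unmixed against
  unit hematoxylin/DAB stain vectors (`OD = C·M`, solved per pixel).
- Per-pixel DAB intensity classes (negative / weak / moderate / strong) from
  explicit concentration cutpoints.
- Tissue mask, watershed nuclei segmentation, nuclei density (objects/mm²)
  and nuclei %SA.
- A five-zone spatial partition (non-tissue / intracellular / capsular /
  paracapsular / interterritorial) from Euclidean distance shells around the
  nuclei, with nearby cells merged into nests.
- Percent stained area, `%SA = 100 · |positive ∩ tissue| / |tissue|`, split
  into territorial and interterritorial components, and the pixel H-score
  `H = 100·(1·f_weak + 2·f_moderate + 3·f_strong) ∈ [0, 300]`.

Per cohort (cylinder rows averaged per case; cases with no immunoreactivity
excluded):

- Mann–Whitney / Kruskal–Wallis rank tests of each metric against binary
  prognostic factors.
- Dichotomization at the third quartile (high = value ≥ Q3), Kaplan–Meier
  curves with 5-year rates, and the log-rank test, for event-free and overall
  survival.
- Cox proportional-hazards regression (Efron ties) with backward Wald
  elimination: covariates with the largest Wald *p* above the stay threshold
  (default 0.1) are removed iteratively; reported as B, SE, Wald, Exp(B) with
  `exp(B ± 1.96·SE)` confidence limits.

A synthetic generator renders core images with exact ground truth (true
masks, zone map, class map, %SA and H-score) and simulates survival cohorts
with exponential hazards log-linear in covariates and in a
high-territorial-staining indicator, so every stage can be validated against
a known truth.

## Worked example

```bash
ihczone demo --out scratch/demo --seed 0
```

prints, for three noise-free synthetic cores (territorial, interterritorial,
mixed staining patterns):

```
synthetic-territorial-0: terr=15.00% inter=0.00% H-score=39.0 density=2199/mm2
synthetic-interterritorial-1: terr=0.00% inter=15.00% H-score=21.0 density=2199/mm2
synthetic-mixed-2: terr=7.65% inter=7.35% H-score=27.7 density=2199/mm2
```

Each line is one quantified cylinder: the territorial pattern puts its whole
15 %SA inside cells and pericellular bands (interterritorial 0), the
interterritorial pattern the reverse; the mixed core splits the same stained
area across both compartments. The H-score reflects both the stained fraction
and the weak/moderate/strong mix (the territorial default mix skews strong,
hence 39 vs 21 at equal stained area). The demo then simulates a 120-case
cohort and writes the full statistics report (rank-test grid, Q3
Kaplan–Meier / log-rank table, Cox summaries) under `scratch/demo/stats/`;
the printed Cox table retains the high-territorial-%SA indicator with
Exp(B) ≈ 2.07 against a simulated true hazard ratio of 2.34.

The same stages are available as a library:

```python
from ihczone import CoreSpec, Pattern, render_core, analyze_core

image, truth = render_core(CoreSpec(pattern=Pattern.TERRITORIAL, seed=7,
                                    noise_sd=0.0))
metrics = analyze_core(image).metrics
print(metrics.terr_vn_sa, truth.true_terr_sa)  # 15.0 vs 15.0
```

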