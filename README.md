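# kneegap

Virtual mechanically-aligned (MA), measured-resection (MR) total knee
arthroplasty simulation and gap-imbalance analysis.

Given a knee — distal femur and proximal tibia articular surfaces (cartilage
included) plus anatomical landmarks — the package:

1. builds the femoral/tibial mechanical axes, the anatomical frame and the
   signed hip–knee–ankle angle (HKA; > 0 varus, ≤ 0 valgus);
2. constructs four posterior femoral reference axes: surgical transepicondylar
   axis (**TEA**), the perpendicular of Whiteside's line (**WSL**), posterior
   condylar axis with 3° external rotation (**PCA**), and the
   flexion–extension axis from circles fitted to the posterior condylar
   sagittal profiles (**FEA**);
3. performs virtual 9 mm resections: distal femoral and proximal tibial cuts
   perpendicular to each mechanical axis, and a posterior femoral cut per
   reference axis, measuring the maximal resected thickness per compartment;
4. assembles extension/flexion gap distances (femoral + tibial thickness per
   compartment) and the imbalance metrics
   **MLI** (lateral − medial gap, per pose) and
   **FEI** (extension − flexion gap, per compartment);
5. runs cohort statistics: group summaries, Welch t-tests, one-way ANOVA with
   Tukey HSD and compact letters, chi-squared tests, balance-rate tables
   (|FEI| ≤ 1/2/3 mm in both compartments) and imbalance histograms.

Because real MRI-derived cohorts are not publicly available, the package
includes a parametric synthetic knee generator (`kneegap.cohort`): condyles
are analytic primitives (distal spheres, posterior circular arcs, flat tibial
plateau facets) with per-compartment cartilage and wear, so every axis and
resected thickness has a closed-form ground truth emitted alongside the
meshes. Cohort sampling emulates an osteoarthritis population with varus
(HKA 8.2 ± 3.6°) and valgus (−3.9 ± 3.4°) subgroups and compartment-biased
wear.

## Command line

```sh
# 1. generate a synthetic cohort (PLY meshes + landmark JSONs + truth table)
kneegap generate --out cohort/ --seed 7 --n-varus 50 --n-valgus 12
# optionally from a YAML spec: kneegap generate --spec spec.yaml --out cohort/

# 2. simulate all resections (one CSV row per knee x method)
kneegap simulate --in cohort/ --out results.csv

# 3. tables, figures and stats JSON
kneegap report --in results.csv --out report/
```

`kneegap generate` writes `cohort_spec.yaml` (all sampling parameters),
`truth.csv` (every drawn per-knee parameter) and `manifest.json`; reruns with
the same seed are byte-identical. Landmark JSON schema (version 1):
`{"schema_version": 1, "side": ..., "landmarks": {name: [x,y,z]},
"regions": {name: [vertex indices]}}` — region names prefixed `femur_` /
`tibia_` index into the corresponding PLY vertex list. Unlabeled meshes fall
back to geometric heuristics (frame-x sign for compartments, posterior band
for the condylar facets).

## Conventions

* lengths in mm, angles in degrees at API boundaries;
* anatomical frame: origin at the intercondylar notch, `z` along the femoral
  mechanical axis (proximal), `x` medio-lateral (lateral-positive), `y`
  anterior; side-aware, so medial/lateral semantics are identical for left
  and right knees;
* cut planes carry the resected material on the positive halfspace; the
  compartment containing the depth-defining extreme point is resected by
  exactly the nominal depth (9 mm default);
* external rotation moves the lateral end of a reference axis posteriorly;
* HKA = 0 is classified as valgus.

## Layout

```
src/kneegap/
  geometry.py   planes, extreme points, rotations, Kåsa circle fit
  anatomy.py    landmarks, frames, HKA, TEA/WSL/PCA/FEA axes
  resection.py  cut-plane construction, resected thickness
  gaps.py       gap distances, MLI/FEI, alignment classification
  cohort.py     synthetic knee generator + cohort sampler (ground truth)
  pipeline.py   per-knee end-to-end simulation
  stats.py      summaries, Welch t, ANOVA/Tukey, chi-squared, balance rates
  report.py     tables, figures, stats JSON
  reference.py  published printed-mean worked examples (data/*.csv)
  io.py         ASCII PLY/STL, landmark JSON, YAML specs, results CSV
  cli.py        generate / simulate / report
```
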