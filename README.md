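# cytocluster

Cell-cluster morphometry for liquid-based endometrial cytology.

Endometrial cancer (EC) and atypical endometrial hyperplasia (AEH) are
usually diagnosed from invasive biopsies; thin-layer (liquid-based)
endometrial cytology is a gentler alternative, but its reading is
subjective.  At low magnification, malignant samples show large cell
clusters with irregular, protruding outlines, while benign clusters
are small, smooth and compact.  `cytocluster` quantifies exactly that:
it binarizes low-magnification field images, measures every connected
cell cluster, and turns the measurements into diagnostic and
prognostic statistics.  It is aimed at cytopathology image-analysis
researchers who want a tested, scriptable version of this workflow —
plus a synthetic cohort generator, since no public image set of this
kind exists.

## What it computes

Per cluster (classical particle analysis): area, perimeter (chain-code
with a corner-corrected option), circularity 4πA/P² (capped at 1),
moment-ellipse major/minor axes and orientation, solidity A/A_hull
(convex hull of pixel corners), and the maximum/minimum Feret
diameters (rotating calipers).  Per field: the box-counting fractal
dimension, D = −d ln N(ε)/d ln ε, of the whole binary mask.  Specimen
values average five fields.

Downstream statistics: logistic odds ratios per descriptor (unadjusted
and adjusted for age ≥ 55 and the dichotomized cytology result),
empirical ROC curves with Mann–Whitney AUC, DeLong confidence
intervals and Youden cutoffs, paired DeLong comparison of cytology
alone versus cytology + descriptor, the binormal ROC sample-size
formula, Kaplan–Meier/log-rank survival, outcome-based ("maximally
selected log-rank") cutpoints with an optional permutation-corrected
p-value, and Cox proportional-hazards models.

## Worked example

Run a quarter-scale synthetic study (51 patients, class mix calibrated
to a published endometrial cytology case series) end to end:

```python
from cytocluster.pipeline import PipelineConfig, run_full_study

cfg = PipelineConfig(
    seed=7,
    counts={"Normal": 23, "EH": 3, "AEH": 4, "EM_G1": 11,
            "EM_G2": 5, "EM_G3": 3, "Others": 2},
    field_size=320, clusters_per_field_mean=5.0)
report = run_full_study(cfg, out_dir="demo/")

d = report["diagnostics"]
print(d["n"], d["n_positive"], round(d["cytology_auc"], 3))
for name in ("circularity", "solidity", "fractal_dimension"):
    e = d["features"][name]
    print(name, round(e["auc"], 3), e["direction"])
```

prints (seed 7):

```
51 25 0.673
circularity 0.992 lower_in_disease
solidity 0.963 lower_in_disease
fractal_dimension 0.838 higher_in_disease
```

Read: of 51 simulated patients, 25 are EC/AEH; the three-tier cytology
alone discriminates with AUC 0.673, while measured circularity (lower
in disease), solidity (lower) and field fractal dimension (higher)
reach AUCs of 0.992, 0.963 and 0.838.  The same report contains, e.g.,
the in-sample combination of fractal dimension with cytology
(AUC 0.894 vs 0.673, DeLong p < 0.001) and, in the cancer subset
(n = 21, 18 deaths), an outcome-based circularity cutpoint of 0.711
(log-rank χ² = 28.5).  `demo/` receives the field images, the cohort
and feature CSVs, and the full JSON report.

The same pipeline is scriptable from a shell:

```bash
cytocluster simulate --out study/ --seed 7
cytocluster extract  --in study/cohort.csv --out study/features.csv
cytocluster diagnose --features study/features.csv --meta study/cohort.csv --out study/dx.json
cytocluster prognose --features study/features.csv --meta study/cohort.csv --out study/surv.json
# or all at once:
cytocluster run-all --out study/ --seed 7
```

## Documentation

The model conventions, generator calibration, numerical choices and
known limitations are documented in [`docs/methods.md`](docs/methods.md).
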