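# Methods

`cytocluster` re-implements, as a tested pipeline, a cell-cluster
morphometry workflow for liquid-based endometrial cytology: low-
magnification field images are binarized, each connected cell cluster
is measured with classical particle-analysis shape descriptors, the
whole binary field gets a box-counting fractal dimension, and the
specimen-level averages feed a diagnostic stage (logistic association
and ROC combination with the cytologic diagnosis) and a prognostic
stage (outcome-based survival cutpoints and Cox models).  Because no
public image set of this kind exists, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes, and every estimator is validated against analytic fixtures or
independent oracles.

## Preprocessing

Images are reduced to 8-bit grayscale (Rec. 601 luminance for RGB,
linear rescale for deeper integer types, rounding half away from zero)
and thresholded.  The default threshold is the iterative intermeans
(isodata) algorithm — the default of the interactive tools this kind of
analysis is usually done with — computed on the 256-bin histogram as
the fixed point of t ← round((μ_{≤t} + μ_{>t})/2); Otsu and fixed
thresholds are available.  Stained clusters in brightfield are dark on
a light background, so the default polarity takes the low side as
foreground.  Two degeneracy guards exist: a constant image has no
threshold, and a data-driven threshold whose two sides differ by fewer
than `min_contrast` (default 30) gray levels indicates an object-free
field of pure sensor noise; both return an all-background mask with a
degenerate flag instead of spurious foreground.

Connected clusters are labeled under 8-connectivity (4 available) and
components below `min_area` = 64 px are discarded as debris; both
values are configurable and logged, and border-touching clusters are
kept by default.  These are declared defaults, not values inferable
from any publication.

## Shape descriptors

All descriptors are computed from the pixel set of one labeled
component.

**Boundary and perimeter.** The outer boundary is traced with Moore
neighbor tracing from the topmost-then-leftmost boundary pixel,
stopping when the initial move repeats.  The chain-code perimeter
weights axial steps 1 and diagonal steps √2.  That convention is exact
for axis-aligned polygons (a 20×20 square measures 4·19 = 76) but
overestimates smooth curves by ≈5% — a digitized line at angle θ
measures (|cos θ| + (√2−1)|sin θ|)⁻¹-fold too long on average, so a
digital circle of r = 50 measures ≈1.0495·2πr.  Because a smooth
cluster should report circularity ≈1, the measurement pipeline defaults
to the Vossepoel–Smeulders corner-corrected estimator

    P = 0.980·N_axial + 1.406·N_diagonal − 0.091·N_corner,

(N_corner = steps whose chain code differs from the previous step),
which is accurate to well under 1% on disks; the plain convention stays
available via `perimeter_chain(..., convention="chain")`.  Degenerate
components get fixed fallbacks that keep circularity finite: a single
pixel has perimeter 4, an axial two-pixel domino 6, a diagonal pair 8.

**Circularity** is 4πA/P², capped at 1 (digitization can push the raw
ratio slightly above it).

**Solidity** is pixel area over the area of the convex hull of the
pixel-corner point set (every pixel contributes its four unit-square
corners; the hull is computed on boundary-pixel corners only, which is
equivalent).  The corner hull contains every foreground unit square,
so solidity cannot exceed 1.  Its discretization bias is O(1/R): a
rasterized disk of radius 30 measures ≈0.97, not 1.0.  Consequently
solidity is only informative about boundary concavity once protrusions
exceed the pixel scale; comparisons between nearly-smooth shapes are
dominated by this bias.

**Ellipse fit.** Axes come from the eigenvalues λ₁ ≥ λ₂ of the second
central moment matrix of the pixel coordinates (full axis length
4√λ), then both axes are rescaled by a common factor so the fitted
ellipse has exactly the component's pixel area.  The angle is the
major-axis orientation in degrees counterclockwise from the x-axis in
[0, 180).  Angle is axial data (period 180°); cross-cluster averaging
therefore defaults to the circular mean on doubled angles, with the
plain arithmetic mean available for strict mimicry of legacy tools.

**Feret diameters.** From the corner hull: the maximum Feret diameter
is the largest vertex-pair distance; the minimum is the smallest
projection width over the rotating-calipers directions (hull-edge
normals), which is exact for convex polygons.

## Box-counting fractal dimension

For box sizes ε ∈ {2, 3, 4, 6, 8, 12, 16, 32, 64} (the conventional
default scan), N(ε) counts the ε×ε grid boxes, anchored at the image
origin, containing at least one foreground pixel; the dimension is the
negated OLS slope of ln N(ε) on ln ε.  Grid-offset minimization
(taking the minimum count over shifted grids) is available but off by
default to match the common tool's default scan.  The dimension is
computed once per *field* on the full binary mask — box counting runs
alongside, not inside, particle analysis — with per-cluster values
available where wanted.

Validation uses deterministic fixtures with analytic dimensions: a
1-px line (1), a filled square (2), the depth-5 Sierpinski carpet on
243² (log 8/log 3, with the individual counts N(3^k) = 8^(5−k) checked
exactly against the IFS construction), the Sierpinski triangle
(log 3/log 2) and the depth-6 Koch island boundary on 2187²
(log 4/log 3).  All are recovered within ±0.05 at these resolutions.
Two finite-size caveats are worth knowing: (i) the estimate for a
*filled* object depends on its size relative to the box range (a disk
filling a 512² field measures ≈1.93, drifting toward 2 as it grows),
so only the scale-covariant property fd(mask, ε) ≈ fd(2·mask, 2ε) is
asserted; (ii) for the same reason, the dominant driver of the field-
level dimension in sparse fields is how much boundary-rich mass is
present — larger, more numerous, rougher clusters raise it.

## Aggregation

Within a field, descriptor means are unweighted means over clusters
(the within-field rule is a declared choice; median or area-weighted
variants would be equally defensible), plus the cluster count and the
field fractal dimension.  The specimen value is the unweighted mean
over its five fields; fields without clusters are excluded from the
descriptor means but the fractal dimension averages over every field
where any foreground exists.  A specimen with fewer than five
contributing fields is flagged.

## Synthetic cohorts

**Cluster shapes** are star-convex blobs: the boundary is
r(θ) = R·(1 + a·Σ_{k=1..K} k^(−β)(u_k cos kθ + v_k sin kθ)) with
standard-normal u, v, rasterized by polygon fill after an elliptical
stretch (eccentricity e, area-preserving).  a = 0 gives an exact
ellipse; a controls boundary roughness/protrusion, β the spectral
decay.  Draws that push r(θ) ≤ 0 raise and are redrawn.  Benign
clusters are small and smooth (R ∈ [14, 24], a ∈ [0.04, 0.14]);
malignant clusters are larger with rougher boundaries, increasing by
grade (up to R ∈ [22, 36], a ∈ [0.20, 0.30], β = 1.1).  Cluster size is
the main driver of the field fractal dimension; roughness drives
circularity and solidity.

**Patient hierarchy.** Each patient first draws an individual
parameter point within the class range; that patient's clusters jitter
around it (±15% radius, ±25% amplitude, ±0.1 eccentricity).  Without
this between-patient level, five-field specimen averages would
concentrate on the class mean and every descriptor would separate the
classes perfectly — which real cohorts do not do.  With it, the
simulated descriptor AUCs span roughly 0.5 (angle) to 0.99
(circularity), qualitatively matching reported clinical orderings.

**Fields** place a Poisson(6) number of clusters (capped at 12)
disjointly — with a 2-pixel margin so 8-connected labeling recovers
them individually — as dark objects (gray 60) on a light background
(gray 220) with Gaussian sensor noise (σ = 8) in 384² fields, five per
specimen.  Thin-layer preparations distribute clusters evenly with
little overlap, which is what the disjoint placement emulates.

**Cohort structure** defaults are calibrated to a published
200-patient endometrial cytology case series: class counts
(Normal 92, EH 13, AEH 17, EM G1 43, EM G2 18, EM G3 10, serous/clear
7), class-conditional ages (normal, truncated at 18; e.g. Normal
49.9 ± 12.2 y, EM G2 63.1 ± 13.8 y), and the three-tier cytology
category drawn per class from the observed cross-tabulation.  Cytology
is conditionally independent of morphology given histology, which
keeps "adjusted for cytology" models meaningful.

**Survival** is exponential: hazard h₀·exp(β·z) with z the cohort-
standardized specimen features (defaults β = −0.7 circularity, −0.7
solidity, +0.7 fractal dimension per SD — low circularity/solidity and
high fractal dimension are the poor-prognosis directions), baseline
h₀ = ln 2/60 per month (5-year median at z = 0).  Censoring is an
independent exponential with rate h₀·c/(1−c) for a target censored
fraction c (default 0.6) plus an administrative cap at 120 months.

A second, purely **tabular generator** draws specimen features directly
from unit-variance class-conditional Gaussians, so a feature's class
separation is known in closed form (AUC = Φ(Δ/√2)); parameter-recovery
tests use it because the ground truth is analytic.  It is also the
honest way to test "the pipeline recovers a designed AUC of 0.85":
no closed-form AUC exists for the image-level generator.

What the generator does *not* emulate: stain and chromatin texture,
nuclear-level structure, overlapping or touching clusters, uneven
illumination, debris and mucus, and menstrual-cycle morphology changes.
Passing tests therefore demonstrate correctness of the measurement and
inference machinery under the stated generative model, not clinical
performance on real slides.

## Diagnostic statistics

The diagnostic label is cancer-or-AEH (histology AEH, EM G1–G3,
serous/clear) versus benign (Normal, EH); age dichotomizes at ≥55
years (inclusive) and cytology at positive-or-suspicious versus
negative.

Logistic fits are maximum likelihood with Wald CIs on the log-odds
scale, reported per-unit as odds ratios, unadjusted and adjusted for
the age and cytology flags.  Complete or quasi-complete separation is
detected (divergent estimates or non-finite standard errors) and
flagged, with the direction of divergence reported from a lightly
ridge-penalized fit rather than a silently diverged one.  Note that
per-unit ORs of descriptors with tiny natural ranges (circularity,
solidity ∈ (0, 1]) are legitimately astronomical or near zero.

ROC analysis uses the empirical curve over midpoint thresholds; the
AUC is the Mann–Whitney statistic with ties counted ½ and a DeLong
placement-value standard error.  The reported cutoff maximizes the
Youden index J = sens + spec − 1, ties broken toward higher
specificity.  Markers are auto-oriented (a marker lower in disease is
negated before the ROC; the direction is reported).

Combining a descriptor with cytology uses the fitted probability of
the two-predictor logistic model, fitted and evaluated in-sample
(apparent performance, matching common clinical practice; no
cross-validation by default).  Paired AUCs are compared with the
DeLong covariance test on placement values; identical or
rank-identical scores give p = 1 by construction.

The ROC sample-size computation follows the binormal variance-function
method: with θ the alternative AUC, a = √2·Φ⁻¹(θ) and
V(θ) = 0.0099·e^(−a²/2)(6a² + 16),

    n = (z_{1−α/2}√V(0.5) + z_{power}√V(θ))² / (θ − 0.5)²

cases per group, rounded to the nearest integer (the only rounding
rule consistent with both published operating points: 40.21 → 40 at
θ = 0.70 and 72.74 → 73 at θ = 0.65, at α = 0.05 two-sided and 90%
power).  Whether published "required cases" are per group or total is
often ambiguous; this implementation returns the per-group count.

## Prognostic statistics

Kaplan–Meier curves carry Greenwood variances; group comparison uses
the log-rank test (k groups, χ² with k−1 df).

The outcome-based cutpoint for a marker scans the midpoints between
consecutive distinct values whose split leaves at least
`min_group_frac` = 0.10 of subjects on each side, and keeps the split
maximizing the two-group log-rank χ² (computed by a vectorized
implementation validated against the reference log-rank to machine
precision).  The nominal 1-df p-value of the maximum is reported
because that is what the clinical software this emulates displays, but
it is anti-conservative by construction (a maximum over many
correlated tests).  An honest p-value is available by permutation:
the marker vector is permuted against the (time, event) pairs and the
scan maximum recomputed, giving the exact finite-sample null of the
selected statistic; the calibration suite verifies ~5% rejection for
the corrected and inflated rejection for the uncorrected version.
Risk-group orientation is explicit per marker (low circularity/
solidity = risk group; high fractal dimension = risk group) and only
affects labeling, not the statistic.

Cox models maximize the partial likelihood with Efron tie handling by
default (Breslow available; they agree to 3+ decimals without ties).
Univariable fits per marker are accompanied by multivariable fits
adjusted for age ≥55, endometrioid histology, and the cluster count.
Singular designs raise; monotone likelihood (a covariate perfectly
ordering the events) is flagged.  Subset presets mirror the usual
clinical panels: all cancers, endometrioid only, and high-grade
(G2–G3) endometrioid.

## Orchestration and determinism

`run_full_study` chains simulate → extract → diagnose → prognose under
one master seed; per-patient streams come from spawned seed sequences,
so results are independent of execution order and byte-identical
across runs.  Every analysis default lives in one configuration object
(YAML round-trip), and stage failures carry the stage name with exit
codes distinguishing configuration, data, and statistical-degeneracy
errors in the CLI.

## Problem sizes

The test suite exercises cohorts of 25–60 image-based patients
(256–320 px fields) and up to 2000 tabular patients; null-calibration
suites use 200–500 replicates and the permutation-corrected cutpoint
is verified with 99 permutations per replicate.  The demo study in the
README uses 51 patients — a quarter-scale version of the calibrated
class mix — which completes in well under a minute; the full
200-patient configuration is the package default for
`cytocluster run-all`.

## Known limitations

* Bit-exact replication of any specific interactive tool's perimeter,
  ellipse, or box-count internals is a non-goal; conventions are
  documented and validated analytically instead.
* Solidity comparisons between nearly-smooth shapes reflect pixel
  discretization more than biology (see above).
* The per-unit odds ratios and hazard ratios of bounded descriptors
  are scale-fragile; per-SD effects are the interpretable quantity.
* The generator's class-conditional morphology is a stylized stand-in;
  none of the simulated clinical performance numbers transfer to real
  cytology.
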