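# Methods

`immunocontext` implements a prognosis pipeline for muscle-invasive
bladder cancer (MIBC) built on quantitative immune-contexture features
from whole-slide, cell-level data.  This note documents the models, the
parameters that matter, the synthetic data the pipeline is validated on,
and the numerical and design choices made where the design was open.

## The analysis in one paragraph

Per patient, cells carry μm coordinates and six marker states (PanCK,
CD3, CD8, CD68, CD163, PD-L1).  The tumour mask is partitioned into a
core and a ±500 μm invasive-front band; 21 phenotype populations are
counted (and density-normalised per mm²) in each region, cross-type
Ripley L statistics are evaluated for ten population pairs at six radii,
and clinical covariates are one-hot encoded — 126 + 60 + 15 = 201 named
features.  Survival is binarized at 60 months (bad = disease death by
the cut-off, good = survived it, censored-earlier = excluded).  Four
classifiers — linear SVM on image features, decision tree on
image+clinical, logistic model on image+spatial, random forest on all —
are each tuned by random search under stratified 5-fold CV on the
training split, refit, and thresholded at the maximum of Youden's J on
their training ROC.  A patient is high-risk when ≥ 2 submodels vote bad
prognosis; the 0–4 vote count is the ensemble's ordinal score.  Risk
groups are compared by AUROC/accuracy/sensitivity/specificity/F1 and by
Kaplan–Meier, log-rank and univariate Cox statistics, against the TNM
baseline (stage IV = high risk).

## Phenotyping

A cell is positive for a marker when the mean min–max-normalised channel
intensity over a circular neighbourhood of radius 11 px around the
nucleus is ≥ 32/256 = 0.125; the tie counts positive, and a constant
channel normalises to all zeros.  Populations are predicates over flags
(immune classes require PanCK⁻): general T = CD3⁺, cytotoxic T = CD8⁺,
M2 = CD163⁺, M1 = CD68⁺CD163⁻, total macrophage = CD68⁺ ∪ CD163⁺ (so
M1 ∪ M2 ⊆ total), PD-L1⁺ split into epithelial (PanCK⁺) and
non-epithelial.  Tumour buds are 8-connected epithelium objects
containing one to four nucleus centres; bud membership overrides other
classes for its cells.  Min–max normalisation makes the 0.125 threshold
scale-free but inflates background on patches that contain no positive
signal for a channel — a known failure mode of per-slide normalisation,
visible in the synthetic round-trip only when a patch has no positive
cell at all.

## Regions

Core = tumour mask eroded by the band radius; front-in = mask minus
core; front-out = dilation minus mask.  Erosion/dilation are computed by
Euclidean distance transforms, exactly equivalent to morphology with a
disc structuring element of radius `band_width / pixel_size` px (rounded
to the nearest pixel) but linear-time on whole-slide masks.  Holes are
filled first (the core is the *main tumour mass*); a tumour thinner than
the band yields an empty core with a warning, not an error.  The three
regions are pairwise disjoint and core ∪ front-in reproduces the filled
mask pixel-exactly.

## Spatial statistics

The cross-type K estimator is the unweighted count normalised by window
area and both population sizes, `K̂ = A/(n_x n_y) Σ 1(d_ij ≤ r)`, with
`L = √(K/π)`; radii are {20, 50, 100, 150, 200, 250} μm and the six L
values enter the classifiers as distinct features (no area-under-curve
summarisation).  No edge correction is applied by default: the radii are
small relative to a slide, so boundary bias is a few percent at worst at
r = 250 μm.  An Ohser translation correction for rectangular windows is
available behind a flag and is what the CSR-calibration checks use,
since in a 1000×1000 μm test window the uncorrected estimator's ≈ 2%
negative boundary bias at r = 50–100 μm is larger than the Monte Carlo
error.  The observation window for per-patient features is the whole
tumour plus the front-out band, and λ_y is computed over that window.
Pairs with an empty source or target population are imputed to the
CSR-neutral value L(r) = r so that missingness carries no signal.

## Survival labels and splitting

Bad ⇔ MIBC death at ≤ 60 months; good ⇔ observed beyond 60 months
regardless of later status; excluded ⇔ any censoring before 60 months —
other-cause death, and also alive-censoring, which extends the same
logic to patients whose 5-year status is unknowable.  Because the
censoring time is independent of the disease process, exclusion is
(approximately) uninformative; note the caveat that under planted
effects risk competition induces a small negative correlation between
exclusion and the true risk score, which grows with the effect size.
Stratified sampling uses round-half-up per-class quotas reconciled by
largest remainder, which reproduces both canonical worked examples
(20% of 75+25 → 15+5; 25% of 78 → 20 test / 58 train).  The default
pipeline splits *after* label exclusion (leakage-safe); splitting before
exclusion is available via a flag.

## Learning

Hyperparameter distributions (our choice; there is no public reference
table):

| family | distribution |
|---|---|
| decision tree | depth ~ U{1..20}, min leaf ~ U{1..20}, impurity ∈ {gini, entropy} |
| random forest | trees ~ U{50..300}, depth ~ U{1..20}, feature fraction ~ U(0.1, 1) |
| SVM | kernel ∈ {linear, rbf}, C ~ log-U(10⁻³,10³), γ ~ log-U(10⁻⁴,10) |
| logistic | penalty ∈ {L1, L2}, C ~ log-U(10⁻³,10³) |
| KNN | k ~ U{1..25} (clamped to n−1), weights ∈ {uniform, distance} |

The forest's tree count is capped at 300 to keep a 200-configuration
search tractable on a single CPU; within this small-sample regime
forest performance is flat in tree count well below that cap.  "Linear
regression" is implemented as a regularised logistic model — the
classification context needs probability scores and signed coefficients
for the post-hoc analysis; a least-squares-on-labels variant was
considered and rejected as strictly worse on every axis the pipeline
uses.  Feature normalisation (z-score) applies to SVM/logistic/KNN and
lives inside the CV pipeline so fold statistics never leak.  Nested CV
uses stratified 2-fold outer / 5-fold inner loops; family selection
maximises mean outer AUROC with ties to the smaller variance, and outer
scores are reported mean ± half-range.  All randomness flows from one
master seed through named `SeedSequence` substreams; a `RowAccessLog`
can be attached to training entry points and records exactly which
patient ids each tuning/fitting stage received.

## Reporting

AUROC is the tie-aware pair-probability; sensitivity defaults to the
good-prognosis orientation (sensitivity = fraction of survivors cleared,
specificity = fraction of eventual disease deaths flagged), with the
positive class an explicit argument.  KM/log-rank/Cox are delegated to
lifelines (Breslow ties, Wald 95% CI); complete separation returns an
infinite-HR sentinel instead of raising.  The TNM baseline scores
patients by ordinal stage for its ROC and calls stage IV high-risk.
Post-hoc importance: impurity decrease (tree/forest) or |coefficient|
with sign (logistic/linear SVM), retaining features strictly above
2×mean (tree, logistic, forest) or 2×median (linear SVM).

## Synthetic cohorts

The generator emulates: disc-shaped tumour masses (radius U(1200, 1800)
μm on a 5×5 mm slide), per-class per-region intensities drawn from
configurable ranges (tumour buds enriched at the front; T cells and M2
macrophages Thomas-clustered, σ = 25–30 μm; others Poisson), buds as 1–4
jittered nuclei, Bernoulli PD-L1 co-expression per class, PanCK⁺
non-bud tumour cells at 200/mm², and clinical covariates with the
frequency profile of a typical radical-cystectomy cohort (age ≈ 66 ± 11,
55% male, T 23/50/27%, N 73/17/10%, M1 35%), with stage mapped
deterministically from TNM (M1 ⇒ IV; node-positive ⇒ IIIB if T4 else
IIIA; T3/T4 N0 ⇒ IIIA; T2N0M0 ⇒ II).  Survival is exponential with
hazard h₀·exp(Σβ·z) over z-scored ground-truth intensities
(h₀ = 0.03/month, chosen to give a ~20-month median at baseline),
an independent other-cause exponential (0.007/month, giving roughly
15–20% exclusions at the 5-year cut-off) and administrative censoring at
113 months.  Masks are rasterised at 8 μm/px — a discretization choice;
the IF-patch pixel size is 0.5 μm/px (a 20× scan).

What the generator does **not** emulate: scanner noise, autofluorescence,
necrosis artefacts, irregular tumour outlines, spatially varying
intensity within a region, or dependence between clinical stage and the
planted image effects.  Passing tests therefore demonstrate that the
pipeline recovers known structure under its own generative assumptions —
correctness and power of the machinery — not clinical performance on
real cohorts.

## Run sizes

Default problem sizes used by the test suite and the acceptance script:
CSR calibration with 60 replicates of 300+300 points; oracle equivalence
on 100 random instances; recovery studies on five cohorts of 400
patients with planted effects β = +1 (TB density, core) and −1
(cytotoxic-T density, front-in), ensemble tuning with a
10-configuration random search per submodel.  The library default for
random search is 200 configurations; the scaled-down search is a run-size
choice for the bundled studies, and recovery quality is insensitive to
it under strong planted effects.

## Known limitations

- The exact composition of the 126/60-feature blocks within the
  published totals is a reconstruction; the schema is explicit, stable
  and overridable, but not guaranteed to match the original list
  feature-for-feature.
- The cross-K window and edge-correction conventions are stated
  assumptions (no public reference); all downstream numbers inherit
  them.
- Whether cytotoxic-T requires CD3 co-positivity is unspecified in the
  panel description; CD8⁺PanCK⁻ alone is used (the markers sit on
  separate panels), and the synthetic generator makes cytotoxic T cells
  CD3⁺CD8⁺ so either convention yields the same population there.
- With a binary high/low risk call and small test sets, Cox HRs are
  occasionally infinite (separation); the sentinel is reported, not
  averaged away.
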