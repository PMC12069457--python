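# Methods

This note documents the models, estimators and numerical choices behind
`timescape`, and what the synthetic cohorts do and do not establish about
real tissue data.

## Pipeline overview

The unit of spatial analysis is one sample: a tissue-microarray core with a
1 × 1 mm region of interest, coordinates in µm with the origin at the
lower-left corner. The pipeline runs per sample through phenotyping,
neighborhood assignment and G-cross estimation, then pools samples for
cohort comparison (one observation per image) and survival modelling (one
observation per sample, clustered by patient).

## Cell phenotyping

Phenotypes are assigned by intensity thresholding against a prioritized
gating hierarchy. Positivity uses a closed bound (intensity ≥ threshold);
thresholds are per-marker configuration values (default 3.0 intensity
units, the approximate geometric midpoint of the default signal model), not
learned — an Otsu-style automatic threshold is available but off by
default. Subtype rules outrank parents (CTL and Th before T; M2 before
TAM), and the reporting taxonomy is deliberately overlapping: a CD3+CD8+
cell is both a CTL and a T cell, which the `is_<type>` boolean columns
capture while the single `phenotype` label stays exclusive. Cells matching
no rule are "other": they count in every denominator but are never a focal
type. The exact NK and M2 gating markers differ between antibody panels;
NKp46 and CD163 are configurable stand-ins.

The H-score is the standard semi-quantitative staining summary
`Σ_k (% of cells at k+) · k`, k ∈ {1,2,3}, bounded by 0 and 300; inputs are
validated to be percentages summing to at most 100.

## Inflammatory neighborhoods

A neighborhood is the union of discs of radius R around anchor cells — cells
positive for every marker of an inflammatory combination. Membership is
equivalently "distance to the nearest anchor ≤ R" (closed bound);
neighborhoods may overlap and membership is monotone in R. The seven
default combinations are CD74·CD44, CD74·MIF, MIF·CD44, CD74·CD44·MIF,
iNOS·mPGES1, iNOS·mPGES1·NT and iNOS·NT; the biologically meaningful radius
range is 20–80 µm with a default of 40 µm, sweepable over {20, 40, 60, 80}.
Anchors are gated on the same cell table as everything else: the package has
a single coordinate frame per sample rather than two co-registered
modalities, a deliberate simplification of multi-modality workflows.
Nearest-anchor queries use a k-d tree and are validated in tests against the
all-pairs brute-force oracle.

Three proportion views are produced per sample: neighborhood prevalence
(members / all cells), cell-type mix within a neighborhood (type ∧ member /
members; row excluded when a neighborhood has no members), and each type's
distribution across neighborhoods (type ∧ member / type count; excluded when
the type is absent). Exclusion, rather than imputation, of undefined
denominators mirrors the zero-variance exclusions of the modelling stages.

## G-cross estimation

`G_ij(r)` is the CDF of the nearest-neighbor distance from type *i* to type
*j*; its homogeneous-Poisson baseline is `1 − exp(−α_j π r²)` with α_j the
target-type intensity. Choices:

* **Edge correction.** Default is the reduced-sample (border) correction:
  at radius r the reference set is restricted to cells at least r from the
  window boundary, making the estimator unbiased at every defined radius but
  undefined (NaN) where the restricted set is empty. The raw estimator is
  kept as an option; its boundary bias is visible but small at core scale
  (≲0.01 at the default densities). Other corrections (Kaplan-Meier-style,
  Hanisch) exist and can give slightly different values; results reported at
  matching radii should state the correction used.
* **Same-type curves** exclude the self-point from its own search.
* **Coincident points** (distance 0) count as satisfied at every r ≥ 0.
* **Grid**: 0–80 µm at 1 µm by default; fixed-radius features at
  {20, 40, 60, 80} µm by linear interpolation (exact at grid points); AUC by
  trapezoid with NaN grid points dropped and the trapezoid re-spanned.
* **Within-neighborhood curves** restrict only the reference cells to
  neighborhood members; target cells remain unrestricted. This reads the
  conditioning as "a focal cell located within the neighborhood" without
  truncating the target process; restricting targets as well is a
  defensible alternative that would measure a different quantity.
* **Pairs with an absent type** in a sample are excluded for that pair
  (feature NaN), and model fits drop them per-feature.
* Samples contribute one curve each; curves are never pooled across cores
  before modelling — intra-patient correlation is handled in the survival
  stage instead.

## Cohort comparison

One beta regression per proportion feature: logit mean link, a single
precision φ (no precision covariates), group indicator as the only
predictor. Responses are compressed with the Smithson–Verkuilen transform
`y' = (y(n−1)+0.5)/n` — always, not only at the boundary, so the estimator
is continuous in the data. Features constant within a group are excluded
before fitting (the likelihood is degenerate there), as are non-converged
fits; neither enters the Benjamini-Hochberg family. FDR is applied per
result family (cell types; neighborhoods; each nested-fraction view), and
significance tiers follow q < 0.05/0.01/0.001. Fitting uses statsmodels'
beta-regression ML implementation behind the module surface. Each image is
one observation, including duplicate cores of a patient; this matches
per-image reporting but means the composition comparison, unlike the
survival models, does not adjust for intra-patient correlation — a known
caveat.

## Survival modelling

Kaplan-Meier with Greenwood variance and log-log confidence bands; the
median is the earliest time the curve reaches 0.5 (missing if never
reached); survival probabilities are also reported at fixed horizons
(default 60 and 120 months). Cox models are univariate, ties handled by the
Efron approximation, and features enter untransformed (Ĝ values in [0,1],
AUC in µm) — coefficients are per unit of the feature as measured. The
variance is the cluster-robust sandwich with score residuals summed within
patient; with singleton clusters it reduces to the ordinary robust
sandwich. Duplicating a patient's record leaves the point estimate
unchanged exactly (with identical covariates the duplicated partial-score
still vanishes at the original optimum under Efron weighting) and the
cluster-robust SE unchanged up to O(1/n) tie-correction terms; the naive SE
shrinks by ≈√2 — the tests assert this at 5e-3 absolute (optimizer
stopping) and 1% relative tolerance respectively. Scan outputs report raw
p-value tiers by default with BH adjustment available as a flag, and strata
with fewer than two events or constant features are skipped with a logged
reason.

## Synthetic cohorts

The generator emulates the *structure* of two-stage tissue-microarray
cohorts; tissue is never simulated at pixel level and no claim is made that
real tumors follow these spatial laws. Defaults, chosen once as realistic
core-scale values:

* **Geometry**: 1000 × 1000 µm window; a "Stage III" arm of 157 patients ×
  2 cores and a "Stage IV" arm of 248 patients with 393 cores (145
  duplicated + 103 singleton) across five metastatic-site strata
  (GI 17%, skin 20%, lymph node 12%, lung 16%, other 35%).
* **Spatial law**: independent homogeneous Poisson per type, baseline
  densities totalling ≈1.4e-3 cells/µm² (≈1400 cells per core), tumor-cell
  dominated. Per-sample, per-type log-normal density multipliers
  (σ_log = 0.5) emulate core-to-core heterogeneity. Optional attraction
  rules add Thomas-style offspring (Poisson counts per parent, isotropic
  Gaussian displacement, σ in µm); offspring falling outside the window are
  re-drawn rather than clipped so the within-window process stays
  stationary and edge-correction tests remain valid.
* **Stage shift**: the IV arm multiplies tumor (×1.5) and CTL (×1.6)
  densities and shrinks B (×0.65), NK (×0.55) and CD3-only T (×0.8),
  reproducing the qualitative stage-shift sign pattern; anchor rates shift
  toward CD74/MIF combinations and away from iNOS combinations.
* **Markers**: log-normal intensities (strictly positive, multiplicative
  noise typical of fluorescence and ion-count data), positive median 10,
  negative median 1, σ_log = 0.25, threshold 3. At these defaults
  thresholding recovers ≥99% of true labels; recovery degrades
  monotonically as σ grows.
* **Anchors**: combination positivity is independent Bernoulli per cell
  (a few % per combination), optionally confined to a random sub-window to
  create spatially coherent neighborhoods.
* **Survival**: exponential event times with hazard
  `λ0 · exp(Σ coef · feature)` on per-sample features aggregated to patients
  by the mean (matching how duplicated cores are summarized), independent
  exponential censoring. Baselines λ0 = ln2/20 and ln2/10 per month give the
  two arms ≈20- and ≈10-month median OS.
* **Scan-recovery preset** (`scan_recovery_config`): 400 patients × 1 core,
  tumor density median 2e-4/µm² with σ_log = 0.8, hazard coefficient −1 on
  the empirical `Ĝ_{CTL,Tumor}(40)`. The wide density spread puts Ĝ(40)
  roughly in [0.2, 0.99] (SD ≈ 0.24), an a priori power calculation
  (SE ≈ 1/(SD·√events) ≈ 0.25 at ≈300 events) giving ≈98% power per
  replicate. Null features use pairs that avoid Tumor as target so they stay
  independent of the hazard.

What passing tests show: the estimators agree with closed forms and
brute-force oracles, and the full pipeline recovers known compositional,
spatial and hazard parameters under the generating model. What they do not
show: robustness to segmentation error, marker spillover, inhomogeneous
tissue architecture (the generator is stationary within a core), informative
censoring, or model misspecification in real cohorts.

## Problem sizes and seeds

All stochastic tests are seeded (hypothesis runs derandomized). Replicate
counts follow the statistical design of each check: 200 replicates for
Poisson-law and envelope checks (500 for the null G-cross envelope), 100
random instances for oracle equivalence (n ≤ 500 points), 100 replicates at
n = 500/group for beta-regression recovery, 1000 random vectors for BH, 50
replicates of 400 patients for the end-to-end scan, and 200 label
permutations for null calibration. Where an experiment's sample size was
otherwise free, it was fixed in advance at the smallest size giving
comfortable power for the configured effect (e.g. 30 patients/arm with a
×2 CTL density ratio for stage-effect recovery). The analysis drivers run a
demo-scale cohort (40 + 60 patients) so each completes in seconds; the
full-shape study generator is `generate_study`.

## Known limitations

* Beta regression treats duplicate cores as independent images (per-image
  reporting); only the survival stage models intra-patient correlation.
* The border correction is one of several legitimate edge corrections;
  absolute Ĝ values are correction-dependent near the window scale.
* The simulator's spatial null is stationary Poisson; real cores exhibit
  tumor/stroma compartmentalization that inflates apparent clustering.
* Exact-zero/one proportions are handled by global compression; inference
  for features concentrated very near the boundary is sensitive to this
  choice.
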