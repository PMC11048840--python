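# Methods

## Scope and data model

The package reimplements a dried-jujube flavor/metabolomics workflow as a
reusable pipeline over four input kinds: volatile relative-content tables
(percent of total peak area, per sample group) with an odor-threshold
library; compound × sample intensity matrices with group labels; HPLC
calibration series plus sample measurements; and GMT-style pathway
annotation. Relative contents are stored as percents (the convention of
published volatile tables), intensities as nonnegative arbitrary units, and
contents on a mg/g dry-weight basis. Compound identifiers are matched
case-insensitively after whitespace trimming, with punctuation preserved —
hyphens and parentheses distinguish isomers such as (E)-2-nonenal, so
stripping them would merge distinct species.

## ROAV aroma scoring

ROAV_i = 100 (C_i/C_max)(T_max/T_i), with the reference compound chosen
*per profile* as the argmax of C/T (ties broken lexicographically for
determinism). The per-profile choice matters: different cultivars have
different dominant odorants, and the packaged three-cultivar table shows a
score of 100 in every cultivar column with two distinct reference
compounds. Compounds lacking a threshold are reported in an `excluded`
list rather than dropped silently (real threshold libraries cover only a
fraction of detected volatiles — 27 of 66 in the packaged study design).
Zero-content compounds score 0, the linear-in-C limit. Classification
boundaries: key strictly above the cutoff (default 1), modifier inclusive
on both ends of [0.1, 1]; both cutoffs are configurable.

Because the reference maximizes C/T, every score lies in [0, 100], and the
score is invariant to common rescalings of contents or thresholds.

Reproduction of the packaged published table is verified at a tolerance
derived from print precision: the published inputs carry three decimals, so
each comparison allows 0.5% relative plus the propagation of ±0.0005 in C_i
and C_max through the formula plus half a printing unit. For abundant
compounds this bound is ~0.5%; for trace compounds (C ~ 0.01%) input
rounding alone moves the score by a few percent, which the published table
itself exhibits (its scores were computed from unrounded contents). The
published key/modifier memberships are reproduced exactly; note the
published narrative's 12-compound "ROAV ≥ 0.1" list is internally
inconsistent with its own table (it omits 3-octanone, max 0.222, and
includes two compounds whose maxima are 0.096 and 0.080); this package
follows the formula and the table.

## Quantification

Calibration is unweighted OLS with intercept on the standard series
(conventionally five levels, 0.05–1.0 mg/mL) — the default treatment of
short HPLC curves; detector response is treated as arbitrary linear units.
Inverse prediction may return negative concentrations near blank; clipping
is the caller's decision. Content = concentration × constant volume /
sample mass.

The sugar–acid panel takes bulk-assay TSC/TAC (anthrone colorimetry,
titration) as inputs rather than summing the chromatographic analytes: bulk
totals routinely exceed the fructose+glucose+sucrose sum, so the analyte
sum is exposed as a separate derived quantity. SAR = TSC/TAC exactly;
published ratios computed from unrounded raw data can differ from the
quotient of rounded printed totals by up to ~2%, a documented discrepancy
rather than something to force.

Group comparison runs Shapiro–Wilk per group and Levene across groups as
*diagnostics* (warning on failure, no hard stop — the gating behavior of
desktop statistics packages is unspecified on failure), one-way ANOVA, and
all-pairs Tukey HSD compact letters: groups sharing a letter do not differ
at α. Tukey HSD is chosen as the post-hoc because the source convention
names only "ANOVA with letters"; letters are assigned greedily in
descending mean order, which is permutation-equivariant under relabeling.

## OPLS-DA

Two-class only (±1 encoding, centered); multi-class questions are posed as
pairwise contrasts, matching how differential selection uses the model. The
fit is the orthogonal-signal-correction NIPALS sequence: w ∝ X'y
(normalized); per orthogonal component, the X-loading of t = Xw is
projected off w, normalized to give w_ortho, and the component t_ortho
p_ortho' is deflated from X; the single predictive component is then
refitted on the filtered matrix. Sign indeterminacy is fixed by forcing the
first nonzero loading entry positive. Predictive and orthogonal scores are
orthogonal by construction (checked to 1e-8 in tests).

- **Scaling** defaults to unit variance (the discriminant-analysis default
  of commercial chemometrics software); pareto and center-only are
  available. Zero-variance variables cannot be unit-variance scaled and are
  dropped with a warning.
- **Q²** uses stratified k-fold CV (default 7 folds, the conventional
  default), refitting scaling and model inside each training split;
  Q² = 1 − PRESS/SS_y. When the smaller class has fewer samples than folds
  — always true for a 3+3 design — folds collapse to leave-one-out with a
  warning. A fold that would lose an entire class is an error.
- **Permutation testing** (default 200 replicates) shuffles labels with a
  seeded generator, refits the full model including CV per shuffle, and
  reports add-one p-values for both R²Y and Q², so p is never exactly 0 and
  equals 1 on label-invariant data.
- **`n_orthogonal="auto"`** adds orthogonal components while CV Q² improves
  by more than 0.01 (cap 5).
- **Degenerate inputs** (X'y numerically zero, e.g. constant X) yield a
  zero model with R²Y = R²X = 0 and zero VIPs rather than an error, so
  permutation tests over degenerate shuffles remain well-defined.

VIP for the single-predictive-component model reduces to
VIP_j = √p·|w_j|/‖w‖, so Σ VIP² = p identically; this normalization is
asserted for every fitted model.

The reference statistics printed for the original 66-VOC and 454-metabolite
matrices (e.g. R²X 0.902, R²Y 0.993, Q² 0.986) are not reproducible because
those matrices are unpublished; the test suite instead pins the model's
*properties* — orthogonality, VIP normalization, PLS1 equivalence at zero
orthogonal components, LOO-oracle equality of Q², permutation-p extremes,
null super-uniformity, and recovery on synthetic class structure.

Hierarchical clustering z-scores variables, then applies agglomerative
linkage (default Euclidean/average; correlation distance and
complete/ward available) over samples; the k=2 cut reproduces the
one-shifted-cultivar grouping on synthetic data.

## Differential selection

log2FC uses raw group means; ε = `epsilon_fc` × max(global median, 1) is
added only when a mean is exactly zero, keeping ratios of positive means
untouched. VIP comes from the pairwise two-group model, not a global one.
The call rule is the strict conjunction VIP > 1 ∧ |log2FC| > 1 with no
multiple-testing correction (the convention of widely targeted
metabolomics); the volcano export therefore uses VIP as its y-axis, since
no p-value exists in the rule. In a contrast "A vs B", A is the numerator:
"up" means higher in A. Reversing a contrast swaps up/down counts exactly
and negates every fold change.

## Enrichment

Standard ORA: p = P[X ≥ k] for X hypergeometric over the background; BH
q-values across tested pathways; the significance flag follows raw
p < 0.05 (q-values are reported for the reader). The background is the
annotated subset of detected compounds (pathway-mapper convention);
pathways with no background member are skipped, and a compound belonging to
several pathways counts once in each. Selected ⊄ background is an error
naming the offenders.

## Synthetic data

Generators define the study conditions used throughout the tests:

- **Intensity matrices**: 3 groups × 3 replicates, 454 compounds across the
  15-class composition of a dried-jujube metabolite panel; lognormal
  baselines (log-mean 11, log-sd 1.5, i.e. median ~6×10⁴ arbitrary units);
  planted effects applied multiplicatively to one group; replicate noise
  lognormal with E[noise] = 1 at CV 0.1 — a declared assumption, as
  within-cultivar biological CV is rarely reported. Ground truth is
  returned for recovery tests (planted |log2FC| = 2 at 3+3 replicates is
  recovered with precision and recall ≥ 0.9).
- **Volatile profiles**: Dirichlet compositions (concentration 0.5, giving
  the sparse dominance-heavy profiles seen in real volatile tables, where a
  single fatty acid can hold ~40% of signal), log-uniform thresholds,
  categories over the 7-category set.
- **Calibration series**: the 5-level grid with uniform true slopes,
  Gaussian response noise, truths returned (slope estimator bias < 1% at
  noise SD 0.5 over 200 replicates).

All generators are bit-reproducible for a fixed seed. What passing tests on
these data do *not* show: real metabolomics exhibits batch effects,
intensity-dependent variance, correlated compound blocks and missing
values, none of which are simulated; recovery rates here are upper bounds
on real-data performance.

## Problem sizes

Tests run the full 454 × 9 design where shape matters and 60–250-compound
matrices for model-fitting checks; permutation tests in tests use 10–50
replicates (the default 200 remains the production setting). These sizes
keep the whole suite under a few seconds while exercising every code path
at the study's replicate structure.

## Known limitations

- OPLS-DA is strictly two-class; no O2PLS, no multi-class scores plot.
- No raw chromatogram handling (mzML/CDF), peak picking, or retention-time
  alignment; inputs begin at integrated tables.
- No odor-threshold prediction or matrix-specific threshold correction;
  thresholds are taken as given (water matrix).
- Enrichment requires compound ids that already match the annotation; no id
  conversion layer.
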