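# Methods

## The problem and the model

Myelodysplastic syndromes (MDS) are clonal marrow disorders whose early,
subclinical presentations are easily missed: routine complete-blood-count
(CBC) instruments only trigger a blood-smear review when a value crosses a
pre-configured alarm threshold (haemoglobin < 80 g/L, platelets < 100 G/L,
...), and moderately cytopenic — or transfused — MDS patients cross none of
them. Modern analyzers, however, measure far more than the 23 routine CBC
parameters: the extended panel modelled here has 126 parameters, the extra
103 "research parameters" being 98 cell population data (CPD) values — the
per-population mean (MN) and standard deviation (SD) of cell volume (V),
conductivity (C) and five light-scatter channels (MALS, UMALS, LMALS, LALS,
AL2) — plus 5 research-use-only (RUO) parameters (LHD, MAF, PDW, EGC,
WNOP). Dysplastic granulocytes are hypogranular and morphologically
heterogeneous, which shifts exactly these scatter moments.

The package builds an **MDS-likelihood score**

    MDS-LS = Σᵢ₌₁¹⁰ Cᵢ·Pᵢ + intercept,

a linear score over ten critical research parameters Pᵢ, and turns it into
a smear-triggering flag (score < 0 ⇒ suspect MDS) plus a probability via a
three-parameter logistic curve. The construction has four stages.

### 1. Eligibility (registry)

CPD parameters are enumerated as 2 statistics × 7 channels × 7 populations
(NE, LY, MO, EO, NRBC, NNRBC, RET) = 98. Two exclusions define the analyzed
set: MAF, being computed from routine CBC values (Hb × MCV / 100), is not a
genuinely unused parameter; and all reticulocyte-derived (RET) parameters
fall outside the basic CBC. That leaves 88 analysis-eligible parameters out
of the 103 research parameters (the registry also exposes the 102-member
"counting" set, research minus MAF only, because both tallies are
conventional). The population list for the CPD block and the 23-name CBC
panel are configurable; the shipped defaults are one consistent enumeration
that reproduces the 23/98/5 tallies, with the 23rd CBC slot filled by MPC
(mean platelet component).

### 2. Three-criterion selection

Three lists over the analyzed parameters:

1. **Univariate screening** — each parameter is compared between groups
   with Student's t-test only when Shapiro–Wilk keeps p > 0.1 in *both*
   groups and Levene's test keeps p ≥ 0.05; any gate failure routes to the
   two-sided Wilcoxon rank-sum test (exact for group sizes ≤ 25, normal
   approximation above). Raw p-values are ranked as −log10 p; the top 12
   form list (i). No multiplicity correction is applied by default (the 5%
   line is the working threshold); a Benjamini–Hochberg option exists.
2. **PCA contribution** — PCA of the column-standardized data; the
   contribution of parameter j to dimension d is 100·v²ⱼd (v the unit
   eigenvector), so each dimension's contributions sum to 100. The 12
   largest dimension-1 contributions form list (ii).
3. **PCA representation** — cos², the squared correlation between a
   parameter and a component. Parameters whose cos² summed over dimensions
   1–2 exceeds 0.6 form list (iii) (truncated to the best 12 if more
   pass; a max-over-axes variant is available behind a flag).

The **critical set** is every parameter present in at least two lists.
Ties anywhere are broken lexicographically so the pipeline is fully
deterministic.

### 3. Split-sample score

At each of 10,000 iterations the cohort (189 subjects at the defaults) is
split uniformly at random, without replacement, into a learning set of 130
and a testing set of 59 (the 130/189 ratio is kept, rounded, for other
cohort sizes). A binomial logistic regression of group on the ten *raw*
parameter values is fitted on the learning set with HEALTHY coded 1 — the
coding is forced by the score's sign convention (negative for MDS). The
iteration's efficiency is the fraction of test subjects whose linear
predictor classifies them correctly under the score ≤ 0 ⇒ MDS rule. The
final Cᵢ and intercept are the medians of the per-iteration draws (with an
odd iteration count each median is an actually-drawn value).

Numerical choices: each fit carries an L2 penalty of strength 1e−6 on the
slopes and none on the intercept, so quasi-separated learning splits —
routine when the groups are well separated — give finite coefficients
instead of divergence; the median across iterations further suppresses any
outlier fits. Splits whose learning half lacks one group are redrawn and
counted. A score of exactly 0 classifies as MDS: for a screening flag the
conservative side is to review the smear. Covariates are deliberately not
standardized (the published score operates in raw parameter units); a
standardization flag exists for sensitivity analyses.

### 4. Probability curve and flags

The score-to-probability map is y(x) = a / (1 + exp((b − x)/c)) with
0 < a ≤ 1 and c < 0. The fitting target is the empirical conditional
probability P(MDS | score ≤ s) evaluated on the grid of observed scores —
the cumulative-ratio reading of an "ecdf" construction, and the one
consistent with a plateau a < 1 at very negative scores. The fit is
constrained nonlinear least squares (trust-region reflective) with
deterministic starting values: a₀ = the maximum observed target, b₀ = the
grid point where the target first reaches a₀/2, c₀ = −IQR(grid)/2. The
constants fitted to the original clinical cohort (a = 0.957, b = −13.11,
c = −15) ship as a preset so new records can be scored without refitting;
under that preset a score of −100 maps to a 95.4% probability of MDS.

Conventional flagging applies 13 threshold rules (Hb < 80 g/L, MCV >
105 fL, MCHC > 36 g/dL, RDW > 22%, Plt < 100 G/L, MPV < 7 fL, %MO > 20,
Abs NE < 1.5, Abs LY > 4.0, Abs MO > 1.5, Abs EO > 1.5, Abs BA > 0.3 G/L,
%NRBC > 2). All comparisons are **strict**: the packaged reference table of
11 published MDS patients contains boundary rows (RDW exactly 22.0, Abs NE
exactly 1.5) that are documented as unflagged, which fixes the convention.
Those 11 patients — no conventional flag, yet all with negative published
scores — are shipped as `mdsls/data/table1_undetected_patients.csv` and are
the package's in-data reference case.

## The synthetic cohort generator

No public record-level data exist for this problem, so the generator
emulates the study conditions: 101 MDS vs 88 healthy subjects, all 126
parameters per subject. Each parameter is an independent truncated normal
(floor 0 for physiological quantities):

- the five conventional CBC parameters with published group moments use
  them exactly — Hb 93.8 ± 18.1 vs 140.2 ± 9.2 g/L, Plt 154.7 ± 143.8 vs
  252.9 ± 48.8 G/L, WBC 4.7 ± 3.8 vs 5.8 ± 1.2 G/L, Abs NE 2.9 ± 2.9 vs
  3.2 ± 0.8 G/L, MCV 99.1 ± 12.3 vs 92.2 ± 4.4 fL;
- the ten critical research parameters are planted at Cohen's d = 1.5
  (strong but not trivial separation) with the clinically observed
  directions: MN scatter values of the NNRBC (whole-leukocyte) channel
  decreased in MDS, SD parameters of neutrophils/monocytes increased;
- every other parameter is identically distributed in the two groups.
  CPD magnitudes are unpublished, so research parameters default to 100
  channel units with SD 10; all planted effects are standardized, never
  absolute.

The ten-member critical set comprises the nine names the source text
enumerates (MN-LALS-NNRBC, MN-LMALS-NNRBC, MN-UMALS-NNRBC, SD-AL2-MO,
SD-AL2-NE, SD-MALS-NE, SD-UMALS-NE, SD-V-MO, SD-V-NE) plus MN-MALS-NNRBC as
the unenumerated tenth, consistent with the described variables-map but
unconfirmed; it is planted with the decreased-mean direction.

Real CPD values are certainly correlated (MN/SD pairs of one channel, Hb
with Hct, ...); the published moments carry no covariance information, so
independence is the default and an equicorrelation knob `rho` (Gaussian
copula through the truncated-normal quantile, preserving marginals and
floors exactly) supports robustness experiments. Consequences of
independence worth knowing when reading test results:

- the cos² criterion selects nothing at d = 1.5 — with independent noise a
  planted variable shares only ≈ 36% of its variance with the group factor,
  below the 0.6 plane threshold — so the critical set is recovered by the
  agreement of lists (i) and (ii). On real, correlated data the cos²
  criterion is informative; here it exercises the code path and the
  threshold logic. A passing recovery test therefore shows the two ranked
  criteria and the intersection logic work, not that cos² selection would
  behave identically on instrument data;
- synthetic efficiencies (≈ 97–99% at d = 1.5) exceed the ≈ 92% reported on
  clinical data, as expected when nuisance correlation and label noise are
  absent. The tests accordingly check *properties* (chance-level efficiency
  under permuted labels, sensitivity/specificity ≥ 0.9, type-I error ≈ 5%
  on null parameters) rather than the clinical point estimates.

## Simulation sizes and tolerances

The package's own test-scale choices: split-sample checks use 200–400
iterations (the median aggregation is stable well below 10,000; the default
remains 10,000 for production runs), selection recovery uses 50 seeds,
permutation uniformity 60 permutations, and the null type-I check pools
600 null parameters across three cohorts with a four-standard-error
binomial band. The probability-curve recovery check constructs a score
grid adaptively from the target curve (step ≤ 0.9/(k·rate) so the
cumulative MDS count stays realizable) and requires 10% relative recovery
of (a, b, c); the exact-target round-trip requires 0.1%.

## Known limitations

- Independence between parameters is a simplification; see above.
- The generator models no transfusion dynamics, longitudinal variation, or
  instrument flags beyond the 13 threshold rules.
- The published efficiency dispersion ("± 6.4 × 10⁻⁴ %") is not
  reproducible from summary data and is not modelled.
- The probability-curve target P(MDS | score ≤ s) tends to the cohort's
  MDS prevalence, not 0, at high scores; the fitted logistic extrapolates
  to 0 beyond the observed grid. This matches the published curve's form
  but means fitted curves are prevalence-dependent and should be refitted
  per population.
- Whether the instrument's own thresholds are strict or inclusive is
  inferred from the boundary rows of the reference table; only the strict
  reading reproduces them.
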