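# Methods

## Data model and assumptions

An abundance table is a samples × metabolites matrix of non-negative
raw peak areas.  A missing cell means the amount was below the limit of
quantification (LOQ) — left-censoring, not absence: the latent value is
small but unknown.  Missingness is therefore carried as a distinct state
(NaN in memory, empty cell on disk) and never as zero.  Metadata carries
group (D/Rs/Ra), donor–recipient pair id, age, sex, BMI and a run-day
block label; annotations carry super-/sub-pathway membership and
microbial/xenobiotic flags.

Raw areas are normalized per metabolite within run-day blocks by
registering the median of *detected* values to 1.00; below-LOQ cells
carry no magnitude and are excluded from medians and left untouched.
Two-cohort analyses first restrict both tables to the intersection of
their metabolite ids.

## Step 1 — detectability

Per metabolite, the detected/missing indicator is compared between
groups.  Paired designs use the exact McNemar test: with b and c
discordant pairs, the two-sided p is min(1, 2·min(P(X≤b), P(X≥b))) for
X ~ Binomial(b+c, ½) (the textbook doubled-minimal-tail convention;
p = 1 with no discordant pairs).  Unpaired designs use
Fisher's exact 2×2 test with the "at most as probable" two-sided rule.
Family-wise control is Bonferroni with strict inequality, p < α/M over
the M analyzed metabolites.  Results carry the three-color display
convention (green / orange = raw-significant only / red = significant
after correction) and the distinct missingness-profile summary.

## Filtering and imputation

A metabolite is discarded when non-detectable in **at least** half the
subjects, overall or within either group.  The ≥ (rather than >)
comparison follows the procedure's own wording; the threshold is a
parameter.  The exclusion list is learned on the exploratory cohort only
and transferred verbatim to the confirmatory cohort.

Remaining missing cells are imputed as round(f · min(observed) +
N(0, σ²)) with f = 0.5 and σ² = 100 by default, clipped to ≥ 1 unit.
The Gaussian noise breaks the ties that constant imputation would
create in variance estimates; it is added on the raw-area scale before
rounding, which is meaningful because raw areas are integer-like
(the generator scales latent values by 10⁴).  The clip at 1 keeps log
transforms defined when minima are tiny.  Sensitivity runs sweep
f ∈ {0.25, 0.5, 0.75, 0.9, 0.95, 0.99, 1.0} and noise on/off; for
strongly changed metabolites the significance calls are expected to be
(and in the test suite are) identical across the sweep.

## Step 2 — univariate comparison

Amounts are compared after natural-log transformation (the base only
rescales fold-changes, not p-values): Welch's t with Satterthwaite
degrees of freedom for unpaired data, the paired t (one-sample t on
within-pair log differences) for paired data, two-sided, at the
Bonferroni threshold α/M.  Zero-variance metabolites get p = 1 with a
warning.  Covariate adjustment: unpaired, OLS of log amount on
group + age + sex + BMI with p from the group coefficient; paired, OLS
of the within-pair difference on age difference, BMI difference and a
sex-match indicator with p from the intercept — the intercept is the
group contrast at zero covariate difference, the natural tested term in
a difference model.

## Step 3 — the pairwise log-ratio network

Relative amounts are more informative than absolute ones (they encode
pathway equilibria and cancel sample-level scaling), so the tested
quantity for each unordered pair (i, j) is the between-group change of
log xᵢ − log xⱼ, using the same t family as step 2.  All K(K−1)/2 tests
are computed at once from group mean vectors and covariance matrices
(var(Lᵢ−Lⱼ) = Sᵢᵢ + Sⱼⱼ − 2Sᵢⱼ), which makes the 650-node case cheap.
Per-sample rescaling provably leaves every p unchanged (compositional
invariance, tested to 1e-12).

The graph keeps edge (i, j) iff p ≥ p_max.  Under the global null the
graph is a single clique; after edge removal its connected components
partition the metabolites, the largest component (ties broken toward
the lexicographically smallest member, with a warning) is the
"no change" set, and every other component holds metabolites whose
relative behaviour changed.

**Calibration of p_max.**  Each null simulation draws independent
log-normal metabolites at the analyzed shape (paired designs simulate
the pair differences directly — differences of independent log-normals
are normal, and the t statistic is scale-free).  Its *critical
threshold* is the largest p_max keeping the graph connected, computed
as the bottleneck (minimum-p) edge of the maximum spanning tree of the
p matrix; a grid-search over all distinct p values gives the same
number exactly (tested on 50 random instances).  The point estimate of
p_max is the order statistic of the simulated critical thresholds at
the 5% target (so the in-sample split fraction is ≤ 5%); its 95% CI
comes from a 2,000-resample bootstrap of that order statistic, and the
operational threshold floors the CI lower bound at two decimals —
truncation downward is the conservative direction (fewer false splits).
Validation re-simulates fresh null data under a different seed and
checks the split rate stays within 5% plus Monte-Carlo error.

Calibrated thresholds grow with the node count at fixed n (≈0.20 at
k = 10 to ≈0.34 at k = 60 for n = 10–20 per group): a larger complete
graph tolerates more edge removal before disconnecting, exactly as
random-graph connectivity theory predicts.  Default n_sim is 10,000;
the bundled drivers and tests use 200–2,000 to keep runs short, which
widens the CI and therefore only makes the operational threshold more
conservative.

Restricted networks re-run the procedure on the metabolites of six
candidate pathway groups (polyamine, tryptophan, urea cycle/arginine &
proline, bacterial or fungal, plasmalogen/lysoplasmalogen, primary or
secondary bile acids), with their own calibration at the reduced node
count and sub-pathway/microbial node attributes for display.

## Step 4 — multivariate selection

PCA checks group separation (full SVD, signs fixed by the largest
loading).  Sparse PLS-DA uses soft-thresholded NIPALS: the weight
vector X'y is shrunk by the (keepX+1)-th largest magnitude so exactly
keepX variables stay nonzero, scores are X w, and X and y are deflated
between components; with keepX = all variables this reduces to ordinary
PLS-DA (checked against an independent PLS implementation).  Defaults
keepX = 20, 2 components — descriptive knobs, not estimates: at these
sample-to-variable ratios cross-validation is not meaningful, so PLS-DA
output is read qualitatively.  The lasso logistic path (L1, unpenalized
intercept, standardized columns, 50 decreasing λ values from the
smallest λ that zeroes every slope) is scored by BIC, which is
deterministic at small n where cross-validation would be noisy.

ORA: with N analyzed metabolites, m in a sub-pathway, n selected and k
selected in the pathway, E = (k/m)/((n−k)/(N−m)) and p = P(X ≥ k) for
X ~ Hypergeometric(N, m, n) — upper tail only, since only
overrepresentation is of interest.  The universe is the set of
metabolites surviving the missingness filter.

## Orchestration

The three comparisons are D vs Rs (paired), D vs Ra (paired) and
Rs vs Ra (unpaired, natural metabolites only — every recipient changes
food/tobacco intake after transplantation, so xenobiotic differences
are uninformative).  Sensitivity analyses: 1:1 matching of each Ra case
to the closest-age same-sex unused Rs control (cases in descending-age
order for determinism; a missing same-sex match falls back to any sex
and is counted), and the all-donors variant for paired comparisons.
Heatmaps cluster samples by Ward linkage on Euclidean distances over
per-metabolite z-scored logs (z-scoring puts metabolites of different
magnitudes on one color scale).  Radar tables report raw-scale
mean(Ra)/mean(Rs) ratios per candidate-pathway metabolite with
dispersions and reference 1.

## Synthetic cohorts

The generator emulates: log-normal amounts (mean mu_log, sd sigma_log,
default 0/1) scaled to integer-like raw areas (×10⁴, rounded); paired
donor/recipient structure via a shared per-pair log intercept giving
within-pair correlation pair_corr (default 0.5) that cancels in ratios
and pair differences; group effects as additive log shifts (separate
recipient-vs-donor and Ra-vs-Rs maps); per-metabolite LOQ placed at the
censor_quantile (default 0.2) of the generated values, everything below
marked missing; round-robin run-day blocks (default 4) with
multiplicative log-normal block factors (sd 0.25).  Defaults mirror the
emulated study's shape: ~650 metabolites, ~40 pairs, ~40% of recipients
with GvHD.  The generator does *not* emulate correlated metabolite
modules, chromatographic drift, adducts or isotope patterns — so
passing recovery tests demonstrate correctness of the procedure under
its own assumptions, not robustness to real-data pathologies such as
inter-metabolite correlation (which mainly affects the effective number
of independent tests).

## Numerical choices and edge cases

- Zero variance with equal means → t = 0, p = 1 (warned); with unequal
  means → p = 0.
- Welch df falls back to 1 when undefined; variance differences in the
  covariance identity are clipped at 0 against rounding.
- Imputed cells are clipped at ≥ 1 unit; detected cells are never
  touched; imputation, simulation and calibration are fully
  deterministic given their seeds.
- The MST bottleneck is snapped back to the exact matrix entry (the
  2 − p edge-weight transform costs one ulp).
- PCA drops constant columns with a warning; ORA flags the degenerate
  all-selected case as an error and E = ∞ when a pathway absorbs the
  entire selection.

## Known limitations

- The univariate and ratio tests assume log-normal amounts; heavy tails
  or strong metabolite correlation inflate the effective family size
  and can make Bonferroni and the calibrated p_max conservative or
  anticonservative in opposite directions.
- The no-change component is a label, not a test: when more than half
  the metabolites change coherently, the largest component is no longer
  the unchanged set.
- BIC lambda selection and keepX = 20 are pragmatic defaults for
  descriptive selection, not tuned estimators.
- Imputation bias grows with the censored fraction; the ≥ 50% filter is
  the guard, and the sensitivity sweep quantifies what remains.
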