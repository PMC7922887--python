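# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study generator

The generator emulates a small untargeted LC-MS case-control study: two
groups of 9–15 subjects, a few thousand RT_mass features per ionization
mode, pooled-QC injections at nominal dilutions 1:3, 1:5, 1:7, and
completely-at-random missing values.

Intensities are log-normal with additive structure on the log scale:

    log I_ij = b_j + s_j·e·1[i ∈ case]·1[j planted] + log d_i + ε_ij

* `b_j` — feature baseline, Normal(11.5, 1.5²) in log ion counts
  (≈ 10⁵ median intensity; the spread gives the realistic several-decade
  dynamic range of untargeted data).
* `e` — planted log-fold-change (`effect_size`, default 2.0 natural-log
  units ≈ 7.4-fold, a clearly-detectable metabolic perturbation at these
  group sizes), applied with a random sign `s_j` per planted feature.
* `d_i` — per-sample dilution factor, log-normal with `dilution_sd = 0.3`
  (urine dilution varies severalfold between neonates).
* `ε_ij` — biological + technical noise, `noise_sd = 0.5` on the log
  scale (≈ 50–65% CV, typical for untargeted urine profiling).
* Defaults `n_case=9 / n_control=10 / n_features=2394` mirror the
  emulated urine cohort and its negative-mode table; `n_discriminant`
  defaults to min(40, n_features), the order of the relevant-feature
  count such a study reports.

QC rows are the undiluted pooled profile times the nominal dilution with
multiplicative technical noise `qc_noise_sd = 0.1` — deliberately smaller
than the biological noise, since QC replicates share the biology and vary
only analytically.

Planted features receive the adduct m/z of bundled metabolites (with 2 ppm
jitter), so annotation can be exercised round-trip; decoy m/z are uniform
on 50–1200 Da inside the instrument's scanning range. Missingness is
completely at random (MCAR).

**What this does not emulate:** intensity-dependent (left-censored)
missingness, retention-time drift, batch effects, chromatographic peak
shapes, and correlated metabolite panels. Consequently a passing test
suite demonstrates that the *procedures* behave as specified under the
stated generative model, not that they are robust to every pathology of
real data. One interaction is worth flagging: half-minimum imputation
assumes missingness means "below detection", while the generator's MCAR
missingness violates that assumption — an MCAR-missing value in a
high-intensity group is imputed far too low, making the group bimodal and
costing univariate sensitivity. This is a faithful rendition of what
half-minimum imputation does to MCAR data, and is why the recovery suites
evaluate the selection machinery at `missing_rate = 0`.

## Preprocessing

* **QC calibration.** Per feature, OLS of QC intensity on nominal
  dilution fraction. Retained iff ≥ 3 non-missing QC observations, R² ≥
  0.7 (configurable) and positive slope; retained features are divided by
  their slope ("response-factor correction", so a corrected QC at
  dilution d has expectation d). Whether the calibration corrects or only
  filters is a flag (`qc_correct_intensities`), since both behaviors are
  defensible readings of QC-based normalization.
* **PQN.** Reference = feature-wise median over study samples (the
  canonical choice). Per sample, the quotient median is computed over
  features with a positive reference and a non-missing value; QC/blank
  rows are normalized against the study reference. The map with a *fixed*
  reference is exactly idempotent; re-estimating the reference from
  normalized data shifts quotients by O(1/√n_features), so
  `pqn_normalize(table, reference=...)` exposes the fixed-reference map.
* **Imputation.** Features missing in > 50% of study samples are dropped;
  remaining missing cells get half the feature's minimum observed value.
* **Log transform.** Applied before scaling/testing (flag
  `log_transform`, default on): the generative model and LC-MS intensity
  data generally are multiplicative, and the log makes planted
  fold-changes additive for the t-test/PLS stages.
* **Scaling.** Mean-centering for untargeted data, autoscaling for
  targeted panels; SD uses the n−1 denominator throughout; zero-variance
  columns are centered, flagged, and never divided.

## Outlier screen

PCA by SVD with a deterministic sign convention (largest-magnitude
loading entry positive). T²_i = Σ_a t²_ia/λ_a with the F-based limit
A(n−1)(n+1)/(n(n−A))·F_γ(A, n−A); Q_i is the squared off-model residual
norm with the Jackson–Mudholkar limit from the residual eigenvalue
moments. γ defaults to 0.95; the default component count is the smallest
A reaching 80% explained variance (capped to keep a residual subspace).
Both defaults are configurable; on noise-dominated data the 80% rule
retains many components and the screen becomes slightly more
trigger-happy than at a small fixed A (2–3), which is the recommended
setting for small cohorts. The F-based limit is calibrated for *new*
observations scored against a model whose retained subspace spans the
population covariance; for training samples both tests are conservative,
which is what makes "no outliers detected" the typical outcome on clean
small-cohort data. Outliers are reported with their statistics and never
removed automatically.

## Univariate arm

Shapiro–Wilk per group at p > 0.10 gates each feature to a pooled
two-sample t-test (both groups pass) or a two-sided Mann–Whitney test
(either fails; constant groups route there with a warning). Mann–Whitney
uses the exact null for n ≤ 20 per group without ties, else the tie- and
continuity-corrected normal approximation. The per-group gate (rather
than a pooled-residual gate) is the stricter declared choice. BH q-values
follow the step-up rule q_(i) = min_{j≥i}(m/j)p_(j) clipped at 1;
relevance is q ≤ δ with δ = 0.10.

## PLS-DA core

The two-class response is a single +1/−1 column, autoscaled — for two
classes this is equivalent to a two-column dummy block and keeps the
algebra minimal. NIPALS extracts components sequentially with deflation
of X (tolerance 1e−10, ≤ 500 iterations; with a single response column
the loop converges in one pass). SSY_a = q_a²·t_a't_a feeds VIP.

* **Post-transformation.** The score space is rotated by the orthogonal
  matrix whose first column is the normalized vector of score–response
  covariances (completed by QR): tp carries all covariance with y, each
  to-column exactly none, the score span and fitted values are unchanged.
  The contract (cov(to, y) = 0 to 1e−8, fitted values to 1e−10, variance
  preserved) is asserted in tests; the construction itself is the
  simplest rotation satisfying it.
* **LDA on scores.** Two-class pooled-covariance LDA with priors; exact
  decision ties go to the larger prior, then lexicographic class order;
  singular pooled covariance is ridge-regularized with ε = 1e−8 and a
  warning.
* **Cross-validation.** Stratified 5-fold (within-class shuffle + round
  robin, deterministic under the seed); scaling, PLS and LDA are all
  re-estimated inside each training fold; test predictions are pooled
  into one confusion matrix and one MCC. Component count = argmax of CV
  MCC, ties to the smallest A.
* **Permutation tests.** The class response is permuted and the complete
  statistic recomputed (including the CV loop for MCC_5-fold);
  p = (1 + #{null ≥ observed})/(n_perm + 1), the add-one estimator that
  never returns 0. In the p ≫ n regime the in-fit MCC saturates at 1 for
  permuted labels too, so p(MCC) is expectedly uninformative there while
  p(MCC_5-fold) retains calibrated power — the pair is reported for
  exactly this diagnostic contrast.

## Stability selection

Per bootstrap subset (stratified, with replacement, at the original group
sizes, so both classes always appear) the PLS-DA model is refitted and
features with VIP above a cutoff are marked; the selection frequency over
`n_boot = 500` subsets is thresholded at a majority (> 0.5).

The cutoff is calibrated at significance level α = 0.05 against a
permutation null: the empirical (1−α) quantile of the **maximum VIP over
features** across `n_null = 100` refits with a permuted class response.
The maximum is the family-wise statistic — it controls the probability
that *any* feature is declared relevant on null data — and VIP is
continuous, so the quantile is well defined. The design alternative,
fixing the per-subset rule at the classical VIP ≥ 1 and calibrating a
threshold on the *maximum selection frequency* under permutation, is
retained as `threshold_mode="max_frequency"` but is not the default: at
these dimensions (tens of samples, hundreds-plus features) the
best-correlated null feature exceeds VIP 1 in essentially every bootstrap
subset, the null max-frequency distribution collapses onto 1.0, and the
procedure can neither select nor calibrate.

Two properties of the default follow from the construction and are
verified by simulation in the test suite: planted features with large
effects are recovered with high probability, and on null data the
any-selection rate stays at or below α (the majority-frequency
requirement makes it mildly conservative). One limitation is inherent to
permutation calibration with strong shared signal: when many features
separate the same two groups, permutations that partially align with the
true split inflate the null maximum VIP, and the cutoff rises — the
selection is then strict, and the union with the univariate arm (the
pipeline's merge step, with provenance) carries the discovery load. This
conservatism also means the multivariate relevant set tends to nest
inside the univariate BH set, matching how such two-arm analyses behave
in practice.

## Annotation and ORA

Adduct masses use the proton mass 1.007276 Da ([M+H]⁺/[M−H]⁻ by default;
Na⁺/K⁺/NH₄⁺ shifts available). The default tolerance, 10 ppm, is
appropriate for a Q-ToF instrument. Annotation confidence levels (1/2/3)
are recorded metadata — inferring them would require MS/MS evidence,
which is out of scope. The bundled database is a curated miniature
(75 metabolites, 25 KEGG-style pathways, masses derived from molecular
formulas and re-validated at load time) standing in for the large public
databases; the ORA universe defaults to it and is overridable.

ORA uses the exact hypergeometric upper tail P(X ≥ k), BH across tested
pathways, flag at q ≤ δ (0.15 untargeted, 0.10 targeted, matching the
two arms' conventions). "Impact" is the covered fraction k/K — an
explicitly simple, declared stand-in for topology-weighted impact, which
requires pathway graph structure this package does not model. Both raw p
and q are exported since plots may want either.

## Clinical statistics

Fisher's exact test is two-sided by the "sum of all tables (fixed
margins) at most as probable as the observed" convention with a 1e−7
relative slack on the probability comparison — the convention standard
statistical packages implement, verified in tests against exact rational
enumeration for every table with N ≤ 40. Summary-level t-tests (pooled
by default, Welch by flag) allow testing printed mean (SD) rows; at a
15 vs 15 scale the two flavors agree to well within rounding. Covariates
summarized as median [IQR] cannot be re-tested from summaries and are
displayed pass-through.

## Problem sizes and numerical conventions

Simulation-based tests run at the emulated study's sizes (9–15 per
group; 500–2394 features) with replicate counts chosen for stable
Monte-Carlo verdicts (50–200 replicates; binomial 99% acceptance bands).
The CV-MCC permutation calibration uses n_perm = 99 inside 200
replicates; stability recovery uses n_boot = 100 per simulation.
Deterministic seeds everywhere; derived seeds stay below 2³¹. Tolerances:
NIPALS 1e−10; orthogonality/covariance contracts 1e−8; exact-arithmetic
comparisons 1e−12.
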