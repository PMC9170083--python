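# Methods

## Generative model

The synthetic cohort generator emulates allele-level bulk RNA-seq of HLA
class I in a donor cohort.  For individual *i*, locus *L*, allele copy
*k* ∈ {1, 2} and condition *c*:

    ln tpm = μ_L + α(a_ik) + g_i + h(H_ik)
             + 1[c = stim]·(δ_L + s(a_ik))
             + Σ_v β_v · d_iv + ε_ikc

| term | meaning | distribution | default |
|------|---------|--------------|---------|
| μ_L  | locus ln-mean tpm | fixed | ln of study-scale means (866/1870/1238 tpm) minus σ²/2 |
| α    | per-allele-name effect | N(0, σ_A²) | σ_A = 0.10 |
| g    | shared per-individual factor | N(0, σ_G²) | σ_G = 0.40 |
| h    | per-founder-haplotype effect | N(0, σ_H²) | σ_H = 0 |
| δ_L  | stimulation ln-fold shift | fixed | ln 2.5 / ln 2.04 / ln 2.11 |
| s    | per-allele stimulation deviation | N(0, σ_S²) | σ_S = 0.05 |
| β_v  | planted cis-eQTL effect per alt dosage | fixed | none |
| ε    | residual, fresh per record/condition | N(0, σ_E²) | σ_E = 0.08 |

All effect parameters live on the natural-log scale (not log2): with
ln-scale effects the within-individual ASE ratio has an exact closed form
in exp(), which anchors the calibration tests below.

Assumptions and deliberate simplifications:

- α is drawn once per allele *name* and shared by all carriers — allele
  lineages have characteristic expression levels.  A per-carrier draw is
  available (`shared_allele_effects=False`) for calibration sampling but
  is off by default.
- g, α and h are shared between conditions of one cohort (paired design);
  only the stimulation terms and residuals differ.  `stim_sigma_a` /
  `stim_sigma_e` optionally substitute reduced-dispersion values under
  stimulation, mirroring the tighter allelic balance seen in stimulated
  cells.
- Haplotypes are drawn i.i.d. from a founder table (no recombination);
  h is drawn once per founder entry, so carriers of the same founder
  share it.  This is what makes inter-locus regressions tighter on a
  shared haplotype than on the heterogeneous second haplotypes.
- Genotypes are sums of founder marker vectors; LD among markers and
  with HLA alleles arises purely from founder sharing.  A "coding"
  marker tagging an allele is one whose founder vector is 1 exactly on
  the haplotypes carrying that allele.
- Stimulation response does not vary by individual — only the per-allele
  deviation σ_S is exposed.  Nothing in the downstream statistics
  requires an individual-level response term, and adding one would be
  unidentifiable from a single paired measurement per individual.

Randomness: one integer seed; fixed draw order (allele effects →
stimulation effects → haplotype effects → haplotype assignment →
individual factors → residuals), with residual streams keyed by
condition so `simulate_expression` calls are order-independent.  What
the generator does **not** emulate: read-level sampling noise, mapping
bias between similar alleles, typing errors, cell-composition shifts
under stimulation, population structure in allele frequencies.  Passing
tests therefore demonstrate correctness of the statistics under the
variance-component model, not robustness to those artifacts.

## ASE and the permutation null

ASE = min/(sum) of the two allele tpm values; homozygotes are excluded
by default (their two copies cannot be distinguished by name; a flag
includes them as min-copy/total).  For a heterozygote,
ASE = 1/(1 + e^{|Δ|}) with Δ = (α₁+ε₁) − (α₂+ε₂): the shared factors g
and h cancel.  When the two allele draws are independent,
Δ ~ N(0, 2(σ_A²+σ_E²)), so

    median ASE = 1 / (1 + exp(0.6745 · √(2(σ_A² + σ_E²))))

(0.6745 = Φ⁻¹(0.75), the half-normal median).  This closed form is
verified at 100,000 draws (tolerance ±0.005) and yields 0.4695 at
(σ_A, σ_E) = (0.10, 0.08), 0.4405 at (0.23, 0.10) and 0.4834 at
(0.06, 0.035) — the balanced, dispersed and stimulated calibrations.

The permutation null shuffles tpm values uniformly among the carrier
slots of each allele name, independently per allele, leaving every
individual's typing and every per-allele tpm multiset intact.  Under the
shuffle the two alleles of an individual acquire independent g draws, so
the null median ASE drops to the value implied by 2σ_G² of extra
variance in Δ (≈0.40 at σ_G = 0.40) while the observed median stays
≈0.47, and the empirical p reaches its minimum 1/(R+1) at R = 1000.
Ties count against rejection (replicate ≥ observed), and the +1
correction keeps the p-value valid at any R.  With σ_G = 0 the
within-allele exchangeability is exact, so the test is exactly
calibrated — checked at 400 seeded cohorts.

Replicates are vectorized: per allele group one uniform permutation per
replicate is drawn as the argsort of i.i.d. uniform keys; per-allele
permutations are applied in lexicographic name order for
reproducibility.  A distributional test confirms the vectorized null
matches the record-level `permute_within_alleles` path.

The paired condition comparison is the Wilcoxon signed-rank test on
per-individual ASE differences (a rank-sum test cannot be paired); zero
differences are dropped, and the reported statistic is the signed rank
sum so that swapping condition labels flips its sign.  Allele-pair
correlations use Spearman's ρ on (lower, higher)-expressed pairs — a
deterministic ordering choice, made explicit because the alternative
(random within-pair ordering) is not reproducible.

## Haplotype analysis

Haplotype assignment is a greedy decomposition against a reference
table: a single compatible reference haplotype is assigned and the
complement derived from the remaining alleles; two compatible reference
haplotypes that jointly exhaust the genotype are both assigned; anything
else is unresolved.  No statistical phasing is attempted.  Expression is
attributed to a haplotype through the allele name, so loci at which an
individual is homozygous are skipped (attribution would be arbitrary).
Inter-locus fits are plain OLS with residual SE = √(RSS/(n−2)); both
locus orientations can be requested since neither is canonical.

## cis-eQTL stage

- QC order: MAF (on non-missing calls) → missingness → HWE (1-df
  chi-square); the fate log records the first failing rule.  Thresholds
  default to MAF ≥ 1%, missingness ≤ 2.5%, HWE p ≥ 1e-5.
- Phenotypes are inverse-normal transformed (average ranks →
  Φ⁻¹((rank−0.5)/n)) and residualized on PCs (column-centered SVD
  scores, standardized).  Missing dosages are mean-imputed per variant
  inside the scan only; the stored matrix keeps NaN.
- Per-variant association is simple linear regression via the
  correlation form; the best variant minimizes nominal p with ties
  broken by TSS distance then variant id.  The cis window is
  [TSS − 1 Mb, TSS + 1 Mb], fully closed, 1-based.
- Gene-level significance: R phenotype permutations (R = 1000 by
  default), null statistic = per-replicate minimum nominal p,
  empirical p = (b+1)/(R+1), plus a Beta(a, b) fit to the null minima
  (method-of-moments start, L-BFGS-B maximum likelihood, moments
  fallback on non-convergence) whose CDF at the observed minimum gives a
  smoothed p usable below the empirical resolution.
- eGene selection is Benjamini–Hochberg on the Beta-approximated gene
  p-values — assumption-light; Storey's procedure can be substituted by
  the caller since π1 machinery is exposed.
- The genotype×stimulation interaction is estimated by regressing the
  per-individual expression difference (stim − unstim) on dosage.  For a
  balanced paired design this is algebraically the fixed
  per-individual-intercept fit of y ~ g + stim + g:stim — the point
  estimate a mixed model would give — without random-effects machinery.
  The reported genotype main effect is the unstimulated stratified
  slope, so slope_stim = main + interaction holds exactly in the
  estimates.
- π1 = 1 − π0 with π0 = #{p > λ}/((1−λ)m) at a single λ = 0.5 (Storey's
  simple estimator); a λ-grid average is available behind
  `pi1_grid`.  Requires m ≥ 20.
- The RNA-PC count is chosen by re-running the scan per candidate k and
  keeping the k with the most FDR-significant genes (ties → smallest k).

Conditional analysis for multiple independent signals per gene and
trans-eQTLs are out of scope.

## Problem sizes and numerical choices

Calibration quantities are measured at the sizes that make their
tolerances meaningful: median-ASE closed forms at 100,000 heterozygous
draws (±0.005); the planted-variant variance explained as a mean over 10
replicated n = 2000 experiments (a single draw of r̂² carries ≈1.4
percentage points of Monte-Carlo SD against a ±2-point tolerance);
permutation-test calibration over 400 seeded 63-donor cohorts at
R = 199 (the rejection decision at α = 0.05 needs only R ≥ 19;
199 keeps the p-grid fine); interaction type-I error over 1000 seeds.
Degenerate inputs are rejected rather than coerced: constant phenotypes
in the inverse-normal transform, monomorphic variants in LD, constant
genotypes in the interaction model, empty cis windows, all-identical
permutation minima in the Beta fit.

## Known limitations

- The permutation null conditions on the observed typing but not on
  condition strata; multi-condition tables must be filtered to one
  condition first (enforced).
- The Beta-approximated gene p assumes the null minima are
  well-described by a Beta law; with very few cis variants the empirical
  p is the more trustworthy number (they are reported side by side).
- Haplotype assignment ignores reference-haplotype frequencies beyond
  tie-breaking and cannot resolve genotypes compatible with ≥3 reference
  haplotypes.
- The interaction estimator assumes one paired measurement per
  individual per condition; unbalanced repeated measures would need a
  true mixed model.
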