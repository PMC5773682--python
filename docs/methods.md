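# Methods

This note documents the models, numerical choices and open design
decisions behind `allergwas`, and what the synthetic-data experiments do
and do not establish about real data.

## Phenotype model and case definitions

Each subject answers, per food, whether they experienced mild or severe
allergic reactions. A subject is a *case* for food *f* if the response is
mild or severe; *controls* are subjects with "none" for all foods and are
shared across the per-food analyses. Mild and severe are pooled into one
case group throughout (the severity flag is carried but never modelled),
because per-food severe counts are too small to analyse separately. A food
enters GWAS only if it has strictly more than `min_cases_per_set` (default
100) cases in *both* samplesets.

## Association model

Per variant, case status is regressed on alternate-allele dosage
(additive coding 0/1/2) plus covariates by Newton–Raphson/IRLS:

    logit P(case) = b0 + b1 * dosage + c' * PCs [+ c2 * dosage_topSNP]

Missing dosages are handled per-variant complete-case, mirroring standard
GWAS tool behaviour. Non-convergence within 25 iterations, a singular
information matrix, or |beta| > 20 (quasi-separation) withholds the
statistics and marks the record non-converged. Covariates are the top two
PCs of the final PCA round, computed once and shared by all foods.
Conditional analysis re-fits the same model with the conditioning variant's
dosage as an extra covariate; when the tested variant *is* (or is perfectly
collinear with, |r| > 1 − 1e−10) the conditioning variant, the record gets
Wald P = 1 by convention, which makes `r2_equiv(A, A) = 1` exactly.

λ_GC is the median association chi-square (from the two-sided P) divided by
the exact 1-df chi-square median, so a uniform P distribution gives 1.0
identically.

## QC choices

* **HWE test form.** Only a threshold is specified upstream, not a test
  form; the default is the classical two-sided exact test (summing all
  heterozygote configurations with probability ≤ the observed one,
  conditional on allele counts), computed by outward recurrence from the
  modal configuration for numerical stability. A 1-df chi-square variant is
  config-selectable (`hwe_test="chisq"`). HWE is computed on all subjects
  of a sampleset — it is a genotyping-QC filter applied before phenotypes.
* **Boundaries.** Call rate and HWE are strict (> 0.99, > 1e−6); MAF is
  inclusive (≥ 0.01); concordance strict (> 0.90); the HLA call-threshold
  filter is strict (CT > 0.5); case-count eligibility is strict (> 100).
* **LD pruning.** Greedy left-to-right scan; a variant is dropped when its
  dosage r² with any retained variant within the preceding window (default
  50 variants; the window/step have no stated upstream values and are
  exposed in config) reaches the threshold. Missing dosages are
  mean-imputed for this screening step only.
* **PCA.** Dosages standardized to mean 2p, SD sqrt(2p(1−p)); constant
  variants skipped; missing entries mean-imputed (zero after
  standardization). Outliers beyond k·SD (default 6) on any top PC are
  removed and the decomposition repeated, by default for three rounds,
  emulating the iterated PCA → outlier-removal → PCA workflow; reference-
  panel co-projection is replaced by synthetic admixed subjects with a
  coherent allele-frequency shift. PC signs are canonicalized (largest
  |loading| positive) so runs reproduce bit-identically.
* **IBD.** Method-of-moments Z0/Z1/Z2 from IBS counts and sample allele
  frequencies, projected onto the simplex by clamping negatives and
  renormalizing; PI_HAT = Z1/2 + Z2. Exact numerical parity with any
  specific external tool is not promised — the estimator is validated at
  the property level (duplicates ≈ 1, unrelated ≈ 0, parent-offspring
  ≈ 0.5).

## Discovery–evaluation and meta-analysis

Both samplesets act simultaneously as discovery and evaluation arms;
candidates pass P ≤ 1e−4 in one arm and P < 0.05 with BH FDR < 0.2 in the
other, in either direction, with no effect-direction concordance
requirement. The FDR universe is not specified upstream: the default
adjusts the evaluation-arm P-values of that direction's discovery-passing
variants only, with a genome-wide alternative behind
`fdr_universe="genomewide"`. The two printed significance cut-offs
(1.21e−7 and 4.4e−9) are stored verbatim as defaults rather than recomputed
(0.05/411521 = 1.215e−7 truncates to the printed 1.21e−7), so tier calls
reproduce printed behaviour. Pooling is fixed-effects inverse-variance;
extreme pooled signals are computed on the log scale
(−log₁₀ P stays finite below the 1e−308 underflow).

## RPE

Count tables hold allele *copies* (two per complete-genotype subject;
subjects missing either allele at a locus are excluded there). Binning
collapses categories with contingency-expected count < 5 in either arm into
a "binned" composite (strict <; membership re-evaluated once after the
merge). The stepwise loop tests the locus (Pearson 2×k), and while
P_locus < 0.05 tests every category (Pearson 2×2, Haldane +0.5 on all
cells only when a cell is zero), records the step, and removes the
lowest-P category entirely from both arms. Because removal is exact count
arithmetic, remaining frequencies equal prior/(1 − f_removed) to machine
precision — the invariant the worked-example checks rely on. The "binned"
composite is never itself removed (it is an artificial aggregate; a config
flag allows it).

Haplotypes are estimated by a standard multi-locus EM over the phase
configurations compatible with each unphased genotype, pooled across cases
and controls, with most-probable-phase *hard* assignment for counting — so
haplotype tables remain integral and the same stepwise arithmetic applies.
Haplotype binning uses the < 1% frequency rule (either arm) instead of
expected counts. Phase-uncertainty propagation is a known limitation;
fractional-count EM output is available from `EmResult.frequencies` but the
stepwise run uses hard counts.

## r2_equiv and eQTL overlap

`r2_equiv = (Z_B − Z_B|A)/Z_A` with Z = −log₁₀ P; inputs of exactly 0 are
floored at 1e−320 before logs. Negative values (conditioning sharpened the
signal) are reported unclamped. Two LD-class rules exist because the
definitions differ by context: the default "or" rule
(r² > t or r²_equiv > t) is used for eQTL work; `equiv_only` is available.

RSS denominators (per-gene minimum P; per gene-tissue for the GTEx-like
dialect, then maximized over tissues) are computed on the *full* database
before restricting to the moderate-LD SNP set, since a gene's top signal is
a property of the resource, not of the GWAS region. The HGVD-like dialect
is prefiltered to R² > 0.1; the ≥ 10-tissue confidence filter applies to
the listing output only (its position relative to the candidate
computation is not specified upstream; listing-only is the default here).

## Synthetic cohort generator

The generator emulates the study conditions: two samplesets (defaults
5751/5628 subjects), 27 grouped foods, 329 duplicate samples, 19 admixed
outliers, control HLA spectra at DRB1/DQB1/DPB1 taken from the published
control frequency columns, DRB1→DQB1 haplotype coupling (default 0.85)
through a partner map of common Japanese haplotypes, and two planted
risk effects (peach DRB1\*09:01 OR 1.67; shrimp DRB1\*04:05–DQB1\*04:01
haplotype OR 1.99), each tagged by a SNP at founder r² 0.8.

Mechanics: founders are haplotypes — per LD block (default 10 SNPs) each
founder copies one of a few ancestral block sequences with a small mutation
rate, so within-block LD is high and between-block LD ≈ 0; subjects draw
two founders, which simultaneously yields SNP dosages, HLA genotypes and
*phased* haplotypes. Tag SNPs are rewritten on founders with carrier-
conditional probabilities a = f + ρ(1−f), b = f(1−ρ) (ρ = √r²_target),
which preserves the tag's allele frequency and hits the target correlation
in expectation; an absent or fixed risk target raises an explicit error.
Per-food case status follows logit p = logit(prevalence) + Σβ·dosage +
group liability, where the liability is a per-subject, per-food-group
Gaussian (default SD 1.0) that induces the cross-reactivity block structure
without modelling shared epitopes. Severity is a post-hoc label on cases
(default 20% severe). Duplicates are byte-identical copies appended with
new ids; admixed subjects are redrawn from a coherently shifted spectrum
(default shift 0.3); missingness is uniform. All randomness flows from one
integer seed through a single generator, giving bit-identical regeneration;
the truth object (causal targets with β, founder assignments, liabilities,
duplicate/admixed ids) serializes to JSON and reloads identically.

Per-food prevalences are free parameters — no published per-food case
counts are bundled — and the default 3% sits in the 1–5% range typical of
self-reported food reactions. Desk-scale runs (hundreds to a few thousand subjects,
tens of SNPs) are used throughout the tests and the acceptance script; the
methods are size-agnostic.

What the generator does *not* emulate: realistic human LD maps and
recombination, chromosome-scale data, imputation dosage uncertainty,
age/sex structure (the emulated cohort is all-female), population-specific
HLA linkage beyond the single partner map, and genotyping batch effects.
Passing tests therefore demonstrate the *statistical machinery* — planted
effects are recovered at the right rates, null calibration holds, exact
arithmetic identities hold — not performance on real LD structure.

## eQTL table generator

Designated SNP-gene pairs get configurable −log₁₀ P in both dialects (and
an HGVD R² above/below the 0.1 prefilter as configured); non-designated
pairs are null with P ~ U(0.01, 1) and R² ~ U(0, 0.1) — below the
variance-explained filter, as expected for SNPs with no real expression
effect. HGVD covers only ~25% of positions by default, mirroring its
sparser array backbone, so the dual-database AND rule is exercised under
missingness.

## Problem sizes and experiment design

The acceptance experiments use: 200 replicates of 1000 cases/4000 controls
(CI coverage of a planted OR 1.9 at MAF 0.13 — Wald coverage checked
against the 93–97% band), 100 cohorts of 2500 subjects (stepwise recovery
of a planted DRB1 allele), one 5000-SNP null GWAS at n = 2000 (λ_GC and
KS uniformity), and 100 synthetic eQTL table pairs (exact candidate
recovery). These sizes give the binomial checks 3-SE headroom while the
whole script stays under a minute.

## Known limitations

* The logistic solver is plain Newton without step-halving; it relies on
  the separation cap rather than line search (adequate for GWAS-scale
  per-variant fits, validated against statsmodels in the tests).
* `ibd_pi_hat` over all pairs is O(n²·m); callers should pass candidate
  pairs for large cohorts.
* VCF support is GT-only and biallelic by design; PLINK binary formats are
  out of scope.
* The cross-reactivity heatmap ordering uses average-linkage clustering of
  the symmetrized matrix; orderings are deterministic but not unique under
  ties.
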