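"""Generate a synthetic two-sampleset cohort and run the QC funnel:
variant filters, duplicate detection by IBD, and iterated PCA."""

import allergwas as ag

cfg = ag.SimConfig(
    n_subjects_per_set=(400, 400), n_snps=200, n_duplicate_pairs=5,
    n_admixed=6, foods=("peach", "apple", "shrimp", "crab"),
    baseline_prevalence=0.1, seed=7)
cohort = ag.simulate_cohort(cfg)
print(f"cohort: {cohort.geno.n_subjects} subjects x "
      f"{cohort.geno.n_variants} variants, "
      f"{len(cohort.truth.duplicate_pairs)} duplicate pairs planted, "
      f"{len(cohort.truth.admixed_ids)} admixed outliers planted")

qc = ag.variant_qc(cohort.geno, duplicate_pairs=cohort.truth.duplicate_pairs)
print(f"variant QC: {len(qc.passing_ids)}/{cohort.geno.n_variants} pass "
      "call-rate >99%, MAF >=1%, HWE P > 1e-6 and concordance >90% in both sets")

geno = cohort.geno.subset_variants(qc.passing_ids)
pruned = geno.subset_variants(ag.ld_prune(geno, 0.2))
print(f"LD pruning at r2 < 0.2 keeps {pruned.n_variants} variants")

kin = ag.ibd_pi_hat(pruned, pairs=cohort.truth.duplicate_pairs)
dups, removals = ag.find_duplicates(kin)
print(f"IBD: {len(dups)} pairs with PI_HAT > 0.8 "
      f"(all planted pairs found: {set(dups) == set(cohort.truth.duplicate_pairs)}); "
      f"{len(removals)} subjects flagged for removal")

rounds = ag.pca_rounds(pruned)
flagged = set(rounds[0].outlier_ids)
planted = set(cohort.truth.admixed_ids)
print(f"PCA round 1 flags {len(flagged)} outliers beyond 6 SD; "
      f"{len(flagged & planted)}/{len(planted)} are the planted admixed subjects")
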