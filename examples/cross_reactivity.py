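"""Cross-reactivity proportion matrix: of subjects reacting to the row
food, which fraction also reacts to the column food?"""

import numpy as np

import allergwas as ag

cfg = ag.SimConfig(
    n_subjects_per_set=(1500, 1500), n_snps=10, n_duplicate_pairs=0,
    n_admixed=0, planted_effects=(), baseline_prevalence=0.08,
    group_liability_sd=1.2,
    foods=("shrimp", "crab", "squid", "peach", "apple", "kiwi", "egg", "milk"),
    seed=13)
cohort = ag.simulate_cohort(cfg)
ph = ag.build_phenotypes(cohort.questionnaire,
                         ag.AnalysisConfig(min_cases_per_set=0))
m = ag.cross_react(ph)
order = ag.order_for_heatmap(m)
print("clustered food order:", order)
print((100 * m.proportions.loc[order, order]).round(1).to_string())
print(f"\nP(react crab | react shrimp) = "
      f"{m.proportions.loc['shrimp', 'crab']:.2f}; "
      f"P(react shrimp | react crab) = {m.proportions.loc['crab', 'shrimp']:.2f}")
# the shared per-group liability produces the block structure: shellfish
# foods co-react with each other far above the ~8% marginal rate, and the
# matrix is asymmetric because the row food's reactor count is the
# denominator.
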