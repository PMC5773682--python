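import numpy as np
import pandas as pd
import pytest

import allergwas as ag
from allergwas.simulate import TagR2Unattainable, simulate_founders

from conftest import make_geno


def small_cfg(**kw):
    base = dict(n_subjects_per_set=(200, 200), n_snps=40, ld_block_size=10,
                n_founder_haplotypes=200, n_duplicate_pairs=5, n_admixed=3,
                baseline_prevalence=0.1,
                foods=("peach", "apple", "shrimp", "crab"), seed=42)
    base.update(kw)
    return ag.SimConfig(**base)


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_same_seed_same_config_bit_identical():
    a = ag.simulate_cohort(small_cfg())
    b = ag.simulate_cohort(small_cfg())
    assert np.array_equal(a.geno.dosages, b.geno.dosages, equal_nan=True)
    assert a.hla.equals(b.hla)
    assert a.questionnaire.equals(b.questionnaire)
    assert a.truth == b.truth


def test_truth_round_trips_through_json(tmp_path):
    c = ag.simulate_cohort(small_cfg())
    c.truth.to_json(tmp_path / "truth.json")
    back = ag.CohortTruth.from_json(tmp_path / "truth.json")
    assert back == c.truth


# ---------------------------------------------------------------------------
# Founder pool and LD structure
# ---------------------------------------------------------------------------

def test_tag_r2_one_is_exact_copy():
    cfg = small_cfg(tag_r2=1.0)
    pool = simulate_founders(cfg)
    eff = cfg.planted_effects[0]
    col = pool.tag_snp[0]
    assert np.array_equal(pool.snp_haplotypes[:, col],
                          pool.carries(eff).astype(np.int8))


def test_tag_r2_realized_in_sampled_subjects():
    """Target tag r2 = 0.8 from a 200-founder pool: empirical dosage r2
    within +-0.1 over 2000 subjects (dosage-correlation oracle)."""
    cfg = small_cfg(n_subjects_per_set=(1000, 1000), tag_r2=0.8,
                    missing_rate=0.0, n_admixed=0, n_duplicate_pairs=0)
    c = ag.simulate_cohort(cfg)
    eff_idx = 0
    eff = cfg.planted_effects[eff_idx]
    carrier = c.founders.carries(eff).astype(np.int8)
    hla_dose = (carrier[c.truth.founder_assignment[:, 0]]
                + carrier[c.truth.founder_assignment[:, 1]]).astype(float)
    tag_id = c.truth.causal_effects[eff_idx]["tag_snp"]
    tag_dose = c.geno.dosage_of(tag_id)
    r = np.corrcoef(hla_dose, tag_dose)[0, 1]
    assert abs(r * r - 0.8) < 0.1


def test_tag_r2_unattainable_is_explicit():
    freqs = {"DRB1": {"04:05": 0.5, "08:03": 0.5}}
    cfg = small_cfg(
        hla_allele_freqs=freqs,
        planted_effects=(ag.PlantedEffect("peach", "hla",
                                          ("DRB1", "09:01"), 2.0),))
    with pytest.raises(TagR2Unattainable, match="absent"):
        simulate_founders(cfg)


def test_within_block_ld_exceeds_between_block():
    cfg = small_cfg(n_subjects_per_set=(800, 800), planted_effects=(),
                    n_admixed=0, n_duplicate_pairs=0, missing_rate=0.0)
    c = ag.simulate_cohort(cfg)
    g = c.geno
    within, between = [], []
    ids = list(g.variants["id"])
    blocks = np.arange(cfg.n_snps) // cfg.ld_block_size
    rng = np.random.default_rng(0)
    for _ in range(150):
        i, j = rng.integers(0, cfg.n_snps, 2)
        if i == j:
            continue
        r2 = ag.dosage_r2(g, ids[i], ids[j])
        if np.isnan(r2):
            continue
        (within if blocks[i] == blocks[j] else between).append(r2)
    assert np.mean(within) > np.mean(between)
    assert np.mean(between) < 0.05


# ---------------------------------------------------------------------------
# HLA spectra and phenotype model
# ---------------------------------------------------------------------------

def test_hla_frequencies_converge_to_spectrum():
    cfg = small_cfg(n_subjects_per_set=(2500, 2500), n_snps=10,
                    n_duplicate_pairs=0, n_admixed=0, low_ct_fraction=0.0)
    c = ag.simulate_cohort(cfg)
    drb1 = c.hla[c.hla["locus"] == "DRB1"]
    alleles = pd.concat([drb1["allele1"], drb1["allele2"]])
    n_copies = len(alleles)
    spec = cfg.hla_allele_freqs["DRB1"]
    for allele in ("09:01", "04:05", "15:01"):
        f = spec[allele]
        se = np.sqrt(f * (1 - f) / n_copies)
        obs = (alleles == allele).mean()
        # founder-pool sampling adds variance beyond binomial: allow pool SE
        pool_se = np.sqrt(f * (1 - f) / cfg.n_founder_haplotypes)
        assert abs(obs - f) < 3 * (se + pool_se)


def test_null_case_fraction_matches_baseline():
    cfg = small_cfg(n_subjects_per_set=(1500, 1500), planted_effects=(),
                    group_liability_sd=0.0, baseline_prevalence=0.05,
                    n_duplicate_pairs=0, n_admixed=0)
    c = ag.simulate_cohort(cfg)
    q = c.questionnaire
    for food in cfg.foods:
        frac = (q.loc[q["food"] == food, "response"] != "none").mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 3000)


def test_planted_effect_raises_case_allele_frequency():
    """OR 1.9 on a 0.131-frequency allele: case allele frequency exceeds
    the control frequency in nearly all seeds (Monte-Carlo sign check)."""
    wins = 0
    for seed in range(20):
        cfg = small_cfg(
            n_subjects_per_set=(400, 400), n_snps=10, n_duplicate_pairs=0,
            n_admixed=0, baseline_prevalence=0.15,
            foods=("shrimp", "crab"),
            planted_effects=(ag.PlantedEffect("shrimp", "hla",
                                              ("DRB1", "04:05"), 1.9),),
            seed=seed)
        c = ag.simulate_cohort(cfg)
        ph = ag.build_phenotypes(c.questionnaire,
                                 ag.AnalysisConfig(min_cases_per_set=0))
        t = ag.count_alleles(c.hla, ph, "DRB1", "shrimp")
        i = t.index_of("04:05")
        wins += t.case_freqs()[i] > t.control_freqs()[i]
    assert wins >= 19


def test_severe_fraction_among_cases():
    cfg = small_cfg(n_subjects_per_set=(1500, 1500), severe_fraction=0.3,
                    planted_effects=(), baseline_prevalence=0.2,
                    n_duplicate_pairs=0, n_admixed=0)
    q = ag.simulate_cohort(cfg).questionnaire
    cases = q[q["response"] != "none"]
    frac = (cases["response"] == "severe").mean()
    assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(cases))


def test_duplicates_identical_before_missingness():
    cfg = small_cfg(missing_rate=0.0)
    c = ag.simulate_cohort(cfg)
    conc = ag.duplicate_concordance(c.geno, c.truth.duplicate_pairs)
    assert (conc == 1.0).all()


def test_too_few_cases_raises():
    cfg = small_cfg(n_subjects_per_set=(15, 15), baseline_prevalence=1e-4,
                    n_duplicate_pairs=0, n_admixed=0)
    with pytest.raises(ValueError, match="case"):
        ag.simulate_cohort(cfg)


def test_admixed_subjects_are_pca_outliers():
    cfg = small_cfg(n_subjects_per_set=(400, 400), n_snps=400,
                    n_admixed=10, admix_freq_shift=0.4, n_duplicate_pairs=0,
                    planted_effects=(), missing_rate=0.0)
    c = ag.simulate_cohort(cfg)
    res = ag.pca_rounds(c.geno)
    assert set(c.truth.admixed_ids) <= set(res[0].outlier_ids)
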