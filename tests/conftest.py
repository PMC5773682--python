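import numpy as np
import pandas as pd
import pytest

import allergwas as ag
from allergwas.io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_geno(dosages, ids=None, sampleset=None, subjects=None):
    """Hand-rolled GenotypeMatrix from a subjects x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    subjects = subjects or [f"S{i:04d}" for i in range(n)]
    ids = ids or [f"v{j:04d}" for j in range(m)]
    variants = pd.DataFrame({
        "chrom": "6", "pos": np.arange(1, m + 1) * 100,
        "id": ids, "ref": "A", "alt": "G"})
    return GenotypeMatrix(subjects, variants, dosages, sampleset)


def make_questionnaire(case_flags, foods, sampleset=None, severe=None):
    """Long-form questionnaire from a subjects x foods boolean array."""
    case_flags = np.asarray(case_flags, dtype=bool)
    n = case_flags.shape[0]
    subjects = [f"S{i:04d}" for i in range(n)]
    sampleset = sampleset if sampleset is not None else ["LL01"] * n
    rows = []
    for i, sid in enumerate(subjects):
        for j, food in enumerate(foods):
            resp = "none"
            if case_flags[i, j]:
                resp = "severe" if (severe is not None and severe[i, j]) else "mild"
            rows.append((sid, sampleset[i], food, resp))
    return pd.DataFrame(rows, columns=["subject_id", "sampleset",
                                       "food", "response"])


@pytest.fixture(scope="session")
def desk_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = ag.SimConfig(
        n_subjects_per_set=(700, 700), n_snps=60, ld_block_size=10,
        n_founder_haplotypes=150, n_duplicate_pairs=6, n_admixed=0,
        baseline_prevalence=0.12, group_liability_sd=0.5,
        missing_rate=0.005, foods=("peach", "apple", "shrimp", "crab"),
        planted_effects=(ag.PlantedEffect("peach", "hla", ("DRB1", "09:01"), 2.3),),
        seed=11)
    return ag.simulate_cohort(cfg)
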