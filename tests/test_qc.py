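import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allergwas as ag
from allergwas.qc import hwe_exact_p, hwe_chisq_p

from conftest import make_geno


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test vs full enumeration oracle
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force exact test: enumerate every heterozygote count
    compatible with the conditional distribution given allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            continue
        # multinomial count of genotype configurations x 2^h phase choices
        w = (math.factorial(n) // (math.factorial(hr) * math.factorial(h)
                                   * math.factorial(hc))) * (2 ** h)
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.mark.parametrize("counts,expected", [
    ((100, 0, 0), 1.0),          # monomorphic
    ((0, 100, 0), None),         # all heterozygotes: extreme excess
    ((25, 50, 25), None),        # exact HWE proportions
])
def test_hwe_reference_points(counts, expected):
    p = hwe_exact_p(*counts)
    if expected is not None:
        assert p == expected
    elif counts == (0, 100, 0):
        assert p < 1e-6
    else:
        assert p >= 0.5


@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_matches_enumeration(hr, het, ha):
    """The recurrence implementation equals the enumeration oracle."""
    if hr + het + ha == 0:
        return
    assert hwe_exact_p(hr, het, ha) == pytest.approx(
        hwe_enumeration_oracle(hr, het, ha), abs=1e-12)


def test_hwe_chisq_alternative_agrees_asymptotically():
    # large balanced sample near equilibrium: both tests are non-significant
    assert hwe_chisq_p(250, 500, 250) > 0.5
    assert hwe_chisq_p(0, 100, 0) < 1e-6


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def test_variant_qc_both_sets_rule(rng):
    """Call-rate failure in one sampleset fails the variant overall."""
    n = 200
    dos = rng.binomial(2, 0.3, size=(2 * n, 3)).astype(float)
    dos[: n // 25, 0] = np.nan        # 96% call rate in LL01 for v0
    dos[:, 1] = 0.0                   # monomorphic v1
    ss = np.array(["LL01"] * n + ["LL02"] * n, dtype=object)
    g = make_geno(dos, ids=["v0", "v1", "v2"], sampleset=ss)
    rep = ag.variant_qc(g)
    assert not rep.pass_overall["v0"]   # fails call rate in one set
    assert not rep.pass_overall["v1"]   # MAF 0
    assert rep.pass_overall["v2"]


def test_variant_qc_hwe_failure():
    dos = np.ones((100, 1))  # every subject heterozygous
    g = make_geno(dos)
    rep = ag.variant_qc(g)
    row = rep.per_set.iloc[0]
    assert row["hwe_p"] < 1e-6 and not rep.pass_overall.iloc[0]


def test_variant_qc_all_missing_variant_fails_not_crashes():
    dos = np.column_stack([np.full(50, np.nan), np.random.default_rng(0)
                           .binomial(2, 0.4, 50).astype(float)])
    g = make_geno(dos)
    rep = ag.variant_qc(g)
    assert not rep.pass_overall.iloc[0]


def test_qc_invariant_to_subject_and_variant_order(rng):
    dos = rng.binomial(2, rng.uniform(0.05, 0.5, 12), size=(150, 12)).astype(float)
    g = make_geno(dos)
    rep1 = ag.variant_qc(g)
    perm_s = rng.permutation(150)
    perm_v = rng.permutation(12)
    g2 = make_geno(dos[np.ix_(perm_s, perm_v)],
                   ids=[f"v{j:04d}" for j in perm_v],
                   subjects=[f"S{i:04d}" for i in perm_s])
    rep2 = ag.variant_qc(g2)
    assert set(rep1.passing_ids) == set(rep2.passing_ids)


# ---------------------------------------------------------------------------
# Duplicate concordance
# ---------------------------------------------------------------------------

def test_duplicate_concordance_definitions():
    dos = np.zeros((4, 10))
    dos[1] = dos[0]                    # S0/S1 identical
    dos[3] = dos[2]
    dos[3, 4] = 2.0                    # one disagreement for S2/S3
    dos[2, 7] = np.nan                 # missing call drops the pair there
    g = make_geno(dos)
    conc = ag.duplicate_concordance(g, [("S0000", "S0001")])
    assert (conc == 1.0).all()
    conc2 = ag.duplicate_concordance(g, [("S0002", "S0003")])
    assert conc2.iloc[4] == 0.0 and np.isnan(conc2.iloc[7])
    both = ag.duplicate_concordance(
        g, [("S0000", "S0001"), ("S0002", "S0003")])
    assert both.iloc[4] == 0.5 and both.iloc[7] == 1.0


def test_duplicate_concordance_error_model(rng):
    """300 pairs with 0.5% per-genotype flip error: mean concordance near
    the Monte-Carlo expectation (both-correct or coincidentally equal)."""
    m, pairs = 200, 300
    base = rng.binomial(2, 0.3, size=(pairs, m)).astype(float)
    err = rng.random((pairs, m)) < 0.005
    noisy = base.copy()
    # flip erroneous genotypes to a different value
    noisy[err] = (noisy[err] + 1 + (rng.random(err.sum()) < 0.5)) % 3
    dos = np.vstack([base, noisy])
    subjects = [f"A{i:04d}" for i in range(pairs)] + \
               [f"B{i:04d}" for i in range(pairs)]
    g = make_geno(dos, subjects=subjects)
    conc = ag.duplicate_concordance(
        g, [(f"A{i:04d}", f"B{i:04d}") for i in range(pairs)])
    assert abs(conc.mean() - 0.995) < 3 * np.sqrt(0.005 * 0.995 / pairs)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_drops_perfect_copy(rng):
    a = rng.binomial(2, 0.4, 300).astype(float)
    b = rng.binomial(2, 0.4, 300).astype(float)
    g = make_geno(np.column_stack([a, a, b]), ids=["x", "x_copy", "y"])
    kept = ag.ld_prune(g, 0.2)
    assert "x" in kept and "x_copy" not in kept


def test_ld_prune_retains_independent(rng):
    dos = rng.binomial(2, 0.4, size=(2000, 10)).astype(float)
    g = make_geno(dos)
    assert len(ag.ld_prune(g, 0.2)) == 10


def test_ld_prune_threshold_one_only_exact(rng):
    a = rng.binomial(2, 0.4, 500).astype(float)
    near = a.copy()
    near[:5] = (near[:5] + 1) % 3      # r2 high but < 1
    g = make_geno(np.column_stack([a, a, near]), ids=["a", "dup", "near"])
    kept = ag.ld_prune(g, 1.0)
    assert kept == ["a", "near"]


# ---------------------------------------------------------------------------
# PCA rounds
# ---------------------------------------------------------------------------

def _geno_with_admixed(rng, n=400, m=400, n_adm=8, shift=0.5):
    p = rng.uniform(0.1, 0.5, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    p_adm = np.clip(p + shift, 0.02, 0.98)
    dos[:n_adm] = rng.binomial(2, p_adm, size=(n_adm, m))
    return make_geno(dos)


def test_pca_flags_admixed_outliers(rng):
    g = _geno_with_admixed(rng)
    res = ag.pca_rounds(g)
    admixed = {f"S{i:04d}" for i in range(8)}
    assert admixed <= set(res[0].outlier_ids)
    # flagged subjects are gone from later rounds
    assert admixed.isdisjoint(res[-1].coordinates.index)


def test_pca_homogeneous_cohort_rarely_flags(rng):
    flagged = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        dos = r.binomial(2, r.uniform(0.1, 0.5, 150), size=(250, 150)).astype(float)
        res = ag.pca_rounds(make_geno(dos))
        flagged += bool(res[0].outlier_ids)
    assert flagged <= 1


def test_pca_constant_variant_skipped(rng):
    dos = rng.binomial(2, 0.4, size=(50, 5)).astype(float)
    dos[:, 2] = 2.0
    res = ag.pca_rounds(make_geno(dos))
    assert np.isfinite(res[-1].coordinates.to_numpy()).all()


def test_pca_reproducible_and_sign_canonical(rng):
    dos = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
    g = make_geno(dos)
    a = ag.pca_rounds(g)[-1].coordinates
    b = ag.pca_rounds(g)[-1].coordinates
    assert np.array_equal(a.to_numpy(), b.to_numpy())
    assert (a.sum() != 0).any()


# ---------------------------------------------------------------------------
# IBD / PI_HAT
# ---------------------------------------------------------------------------

def _haplo_pool(rng, n_h=400, m=2000):
    return (rng.random((n_h, m)) < rng.uniform(0.1, 0.9, m)).astype(np.int8)


def test_pi_hat_duplicates_unrelated_parent_offspring(rng):
    pool = _haplo_pool(rng)
    # disjoint founder haplotypes so the only sharing is the one we build in
    pa = (pool[0], pool[1])
    pb = (pool[2], pool[3])
    child = (pa[rng.integers(2)], pb[rng.integers(2)])
    rows = [pa[0] + pa[1],            # P1
            pa[0] + pa[1],            # exact duplicate of P1
            pb[0] + pb[1],            # P2 (unrelated to P1)
            child[0] + child[1]]      # offspring of P1 x P2
    g = make_geno(np.array(rows, dtype=float),
                  subjects=["P1", "P1dup", "P2", "child"])
    res = {r.pair: r for r in ag.ibd_pi_hat(g)}
    assert res[("P1", "P1dup")].pi_hat >= 0.95
    assert abs(res[("P1", "P2")].pi_hat) <= 0.1
    assert abs(res[("P1", "child")].pi_hat - 0.5) <= 0.1
    assert abs(res[("P2", "child")].pi_hat - 0.5) <= 0.1
    z = res[("P1", "child")]
    assert abs(z.z0 + z.z1 + z.z2 - 1) < 1e-12


def test_find_duplicates_flags_first_by_id(rng):
    pool = _haplo_pool(rng, 200, 1000)
    a = (pool[0] + pool[1]).astype(float)
    b = (pool[2] + pool[3]).astype(float)
    g = make_geno(np.array([a, a, b]), subjects=["S2", "S1", "S3"])
    res = ag.ibd_pi_hat(g)
    dups, removals = ag.find_duplicates(res)
    assert dups == [("S2", "S1")]
    assert removals == ["S1"]
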