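import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import allergwas as ag
from allergwas.rpe import (AlleleCountTable, BINNED, allele_test, bin_rare,
                           count_alleles, em_haplotypes, locus_test, rpe_run)

from conftest import make_questionnaire


def table(case, control, cats=None, locus="DRB1"):
    cats = cats or [f"a{i}" for i in range(len(case))]
    return AlleleCountTable(locus, cats, np.array(case), np.array(control))


def _pheno_for(case_ids, ctrl_ids, food="peach"):
    subjects = sorted(set(case_ids) | set(ctrl_ids))
    flags = np.array([[s in case_ids] for s in subjects])
    q = make_questionnaire(flags, [food])
    q["subject_id"] = np.repeat(subjects, 1)
    return ag.build_phenotypes(q, ag.AnalysisConfig(min_cases_per_set=0))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def test_count_alleles_copies():
    hla = pd.DataFrame({
        "subject_id": ["c1", "c2", "c3", "k1"],
        "locus": ["DRB1"] * 4,
        "allele1": ["09:01", "09:01", "09:01", "04:05"],
        "allele2": ["09:01", "09:01", "04:05", "04:05"],
        "ct": [1.0] * 4})
    ph = _pheno_for({"c1", "c2", "c3"}, {"k1"})
    t = count_alleles(hla, ph, "DRB1", "peach")
    i = t.index_of("09:01")
    assert t.case[i] == 5                       # 2+2+1 copies
    assert t.case[t.index_of("04:05")] == 1     # heterozygote: one copy
    assert t.control[t.index_of("04:05")] == 2
    assert t.case.sum() == 6 and t.control.sum() == 2


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def test_bin_rare_strict_boundary():
    # category totals of 10 in a balanced 200-copy table: expected exactly
    # 5.0 per arm -> NOT binned (strict <)
    t = table([5, 95], [5, 95])
    out = bin_rare(t, 5.0)
    assert BINNED not in out.categories
    # a clearly rare category is collapsed
    t2 = table([1, 499, 500], [1, 499, 500])
    out2 = bin_rare(t2, 5.0)
    assert BINNED in out2.categories
    assert out2.case[out2.index_of(BINNED)] == 1


def test_bin_rare_no_change_when_all_common():
    t = table([50, 60], [55, 45])
    assert bin_rare(t, 5.0).categories == t.categories


# ---------------------------------------------------------------------------
# Locus and allele tests
# ---------------------------------------------------------------------------

def test_locus_test_hand_value():
    stat, df, p = locus_test(table([10, 90], [20, 80]))
    assert stat == pytest.approx(3.9216, abs=1e-4)
    assert df == 1
    stat0, _, p0 = locus_test(table([30, 70], [30, 70]))
    assert stat0 == 0.0 and p0 == 1.0


def test_locus_test_matches_textbook_oracle(rng):
    """Hand-rolled Pearson statistic equals scipy's (uncorrected) on random
    2xk tables to 1e-10."""
    for _ in range(25):
        k = int(rng.integers(2, 10))
        case = rng.integers(1, 500, k)
        ctrl = rng.integers(1, 500, k)
        stat, df, p = locus_test(table(list(case), list(ctrl)))
        ref = chi2_contingency(np.vstack([case, ctrl]), correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_locus_p_uniform_under_null(rng):
    from scipy.stats import kstest
    ps = []
    for _ in range(400):
        probs = rng.dirichlet(np.ones(4) * 5)
        case = rng.multinomial(600, probs)
        ctrl = rng.multinomial(900, probs)
        if case.min() == 0 or ctrl.min() == 0:
            continue
        ps.append(locus_test(table(list(case), list(ctrl)))[2])
    assert kstest(ps, "uniform").pvalue > 0.01


def test_allele_test_or_from_frequencies():
    """The 2x2 OR equals the frequency-odds formula."""
    t = table([225, 775], [148, 852], cats=["09:01", "rest"])
    _, p, or_ = allele_test(t, "09:01")
    assert or_ == pytest.approx(
        ag.odds_ratio_from_freqs(0.225, 0.148), rel=1e-12)
    assert round(or_, 2) == 1.67
    _, p_eq, or_eq = allele_test(table([50, 50], [50, 50]), "a0")
    assert or_eq == 1.0 and p_eq == pytest.approx(1.0)


def test_allele_test_haldane_on_zero_cell():
    t = table([0, 100], [10, 90])
    _, _, or_ = allele_test(t, "a0")
    assert or_ == pytest.approx((0.5 * 90.5) / (100.5 * 10.5))


# ---------------------------------------------------------------------------
# Stepwise RPE
# ---------------------------------------------------------------------------

def test_rpe_renormalization_exact():
    """After removal, per-arm frequencies equal prior/(1 - f_removed)."""
    t = table([400, 120, 80, 1400], [300, 100, 100, 1500])
    f_case0 = t.case_freqs()
    trace = rpe_run(t, ag.AnalysisConfig(bin_min_expected=0.0))
    assert len(trace.steps) >= 2
    removed = trace.steps[1].excluded[-1]
    i = t.index_of(removed)
    step1 = trace.steps[1].stats.set_index("category")
    for cat in t.categories:
        if cat == removed:
            continue
        j = t.index_of(cat)
        expect = f_case0[j] / (1 - f_case0[i])
        assert step1.loc[cat, "freq_cases"] == pytest.approx(expect, abs=1e-12)
    # frequencies sum to one at every step
    for s in trace.steps:
        assert s.stats["freq_cases"].sum() == pytest.approx(1.0, abs=1e-9)
        assert s.stats["freq_controls"].sum() == pytest.approx(1.0, abs=1e-9)


def test_rpe_stops_when_locus_nonsignificant():
    t = table([100, 100, 100], [101, 99, 100])
    trace = rpe_run(t)
    assert len(trace.steps) == 1
    assert trace.steps[0].excluded == ()
    assert trace.termination == "locus_nonsignificant"
    assert trace.steps[0].locus_p >= 0.05


def test_rpe_excluded_list_grows_and_binned_never_removed(rng):
    case = [500, 300, 200, 2, 3, 995]
    ctrl = [300, 400, 300, 3, 2, 992]
    trace = rpe_run(table(case, ctrl))
    seen = set()
    prev = -1
    for s in trace.steps:
        assert len(s.excluded) > prev
        prev = len(s.excluded)
        seen |= set(s.excluded)
    assert BINNED not in seen


def test_rpe_errors_on_degenerate_table():
    with pytest.raises(ValueError):
        rpe_run(table([10], [10]))


# ---------------------------------------------------------------------------
# EM haplotypes
# ---------------------------------------------------------------------------

def _hla_frame(genos):
    rows = []
    for i, g in enumerate(genos):
        for locus, (a1, a2) in g.items():
            rows.append((f"s{i}", locus, a1, a2, 1.0))
    return pd.DataFrame(rows, columns=["subject_id", "locus", "allele1",
                                       "allele2", "ct"])


def test_em_deterministic_phase_for_homozygotes():
    hla = _hla_frame([
        {"DRB1": ("09:01", "09:01"), "DQB1": ("03:03", "03:03")},
        {"DRB1": ("04:05", "04:05"), "DQB1": ("04:01", "04:01")},
    ])
    em = em_haplotypes(hla, ("DRB1", "DQB1"))
    assert em.frequencies[("09:01", "03:03")] == pytest.approx(0.5)
    assert em.frequencies[("04:05", "04:01")] == pytest.approx(0.5)


def em_grid_oracle(hla, loci, step=0.02):
    """Brute-force ML over the haplotype frequency simplex (coarse grid with
    local refinement), independent of the EM code path."""
    em = em_haplotypes(hla, loci)   # only to enumerate the haplotype space
    haps = sorted(em.frequencies)
    geno_pairs = []
    wide = {}
    for _, r in hla.iterrows():
        wide.setdefault(r["subject_id"], {})[r["locus"]] = (r["allele1"],
                                                            r["allele2"])
    from allergwas.rpe import _compatible_pairs
    for s, g in wide.items():
        geno = tuple(tuple(sorted(g[l])) for l in loci)
        geno_pairs.append(_compatible_pairs(geno))

    def ll(freqs):
        f = dict(zip(haps, freqs))
        tot = 0.0
        for pairs in geno_pairs:
            lik = sum(f[h1] * f[h2] * (2 if h1 != h2 else 1)
                      for h1, h2 in pairs)
            if lik <= 0:
                return -np.inf
            tot += np.log(lik)
        return tot

    best, best_ll = None, -np.inf
    grid = np.arange(0.0, 1.0 + 1e-9, step)
    for combo in itertools.product(grid, repeat=len(haps) - 1):
        if sum(combo) > 1 + 1e-9:
            continue
        freqs = list(combo) + [1.0 - sum(combo)]
        v = ll(freqs)
        if v > best_ll:
            best, best_ll = freqs, v
    # local refinement around the coarse optimum
    for _ in range(3):
        step /= 5
        centre = best[:-1]
        ranges = [np.clip(np.arange(c - 2 * step * 5, c + 2.01 * step * 5,
                                    step), 0, 1) for c in centre]
        for combo in itertools.product(*ranges):
            if sum(combo) > 1 + 1e-9:
                continue
            freqs = list(combo) + [1.0 - sum(combo)]
            v = ll(freqs)
            if v > best_ll:
                best, best_ll = freqs, v
    return dict(zip(haps, best)), best_ll


def test_em_matches_grid_search_mle_on_toy():
    """Two-locus toy: EM lands on the grid-search maximum likelihood."""
    hla = _hla_frame([
        {"L1": ("A", "A"), "L2": ("B", "B")},
        {"L1": ("A", "a"), "L2": ("B", "b")},     # double heterozygote
        {"L1": ("a", "a"), "L2": ("b", "b")},
    ])
    em = em_haplotypes(hla, ("L1", "L2"))
    oracle, _ = em_grid_oracle(hla, ("L1", "L2"))
    for h, f in oracle.items():
        assert em.frequencies[h] == pytest.approx(f, abs=1e-4)
    # the ML solution puts all mass on the coupling haplotypes
    assert em.frequencies[("A", "B")] == pytest.approx(0.5, abs=1e-4)
    assert em.frequencies[("a", "b")] == pytest.approx(0.5, abs=1e-4)


def test_em_recovers_simulated_frequencies(rng):
    true = {("A", "B"): 0.5, ("A", "b"): 0.2, ("a", "B"): 0.2,
            ("a", "b"): 0.1}
    haps = list(true)
    probs = np.array(list(true.values()))
    n = 2000
    draw = rng.choice(len(haps), size=(n, 2), p=probs)
    genos = []
    for h1, h2 in draw:
        a = haps[h1]
        b = haps[h2]
        genos.append({"L1": (a[0], b[0]), "L2": (a[1], b[1])})
    em = em_haplotypes(_hla_frame(genos), ("L1", "L2"))
    for h, f in true.items():
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert abs(em.frequencies[h] - f) < 3 * se + 0.01
    assert em.converged


def test_haplotype_rpe_bins_rare_and_requires_k2(rng):
    cfg = ag.AnalysisConfig(min_cases_per_set=0)
    # one common haplotype world: k < 2 after binning -> clear failure
    genos = [{"L1": ("A", "A"), "L2": ("B", "B")} for _ in range(50)]
    hla = _hla_frame(genos)
    flags = np.array([[i < 20] for i in range(50)])
    q = make_questionnaire(flags, ["peach"])
    q["subject_id"] = [f"s{i}" for i in np.repeat(range(50), 1)]
    ph = ag.build_phenotypes(q, cfg)
    with pytest.raises(ValueError, match="fewer than 2"):
        ag.haplotype_rpe(hla, ("L1", "L2"), ph, "peach", cfg)
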