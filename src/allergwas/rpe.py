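"""Relative Predispositional Effects (RPE) analysis of multi-allelic HLA
count tables.

RPE exposes secondary allele effects masked by a strong primary one: the
locus is tested with a Pearson chi-square on the 2xk case/control-by-allele
table; while the locus stays significant, each allele is tested in its 2x2
collapse, the lowest-P ("top effect") allele is removed entirely from both
cases and controls, and the locus is re-tested.  After removal, each
remaining allele's per-arm frequency equals its previous frequency divided
by (1 - removed frequency) in that arm.  Rare categories (expected count
below five in either arm) are collapsed to a "binned" composite before
testing; binned is never itself chosen for removal (configurable).

Haplotype analysis estimates multi-locus haplotypes by EM over the phase
configurations compatible with each unphased genotype, hard-assigns each
subject its most probable phase so count tables stay integral, bins
haplotypes rarer than 1% in either arm, and runs the same stepwise
procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .assoc import PhenotypeTable

BINNED = "binned"


@dataclass
class AlleleCountTable:
    """2 x k table of case/control allele (or haplotype) copy counts."""

    locus: str | tuple
    categories: list[str]
    case: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.case = np.asarray(self.case, dtype=np.int64)
        self.control = np.asarray(self.control, dtype=np.int64)
        if (self.case < 0).any() or (self.control < 0).any():
            raise ValueError("negative counts")
        if not (len(self.categories) == self.case.size == self.control.size):
            raise ValueError("category/count length mismatch")

    @property
    def k(self) -> int:
        return len(self.categories)

    def case_freqs(self) -> np.ndarray:
        return self.case / self.case.sum()

    def control_freqs(self) -> np.ndarray:
        return self.control / self.control.sum()

    def index_of(self, category: str) -> int:
        return self.categories.index(category)

    def without(self, category: str) -> "AlleleCountTable":
        """Remove one category's copies entirely from both arms."""
        i = self.index_of(category)
        keep = [j for j in range(self.k) if j != i]
        return AlleleCountTable(self.locus,
                                [self.categories[j] for j in keep],
                                self.case[keep], self.control[keep])

    def merged(self, categories: list[str],
               name: str = BINNED) -> "AlleleCountTable":
        drop = set(categories)
        keep = [c for c in self.categories if c not in drop]
        case = [self.case[self.index_of(c)] for c in keep]
        ctrl = [self.control[self.index_of(c)] for c in keep]
        case.append(sum(self.case[self.index_of(c)] for c in drop))
        ctrl.append(sum(self.control[self.index_of(c)] for c in drop))
        return AlleleCountTable(self.locus, keep + [name],
                                np.array(case), np.array(ctrl))


def count_alleles(hla: pd.DataFrame, pheno: PhenotypeTable, locus: str,
                  food: str) -> AlleleCountTable:
    """Tabulate allele copies at one locus for a food's cases vs the shared
    controls.  Each complete-genotype subject contributes two copies;
    subjects missing at the locus (no row) are excluded."""
    sub = hla[hla["locus"] == locus]
    case_ids = set(pheno.case_flags.index[pheno.case_flags[food]])
    ctrl_ids = set(pheno.is_control.index[pheno.is_control])
    case_counts: dict[str, int] = {}
    ctrl_counts: dict[str, int] = {}
    for _, row in sub.iterrows():
        sid = row["subject_id"]
        if sid in case_ids:
            d = case_counts
        elif sid in ctrl_ids:
            d = ctrl_counts
        else:
            continue
        for allele in (row["allele1"], row["allele2"]):
            d[allele] = d.get(allele, 0) + 1
    cats = sorted(set(case_counts) | set(ctrl_counts))
    return AlleleCountTable(
        locus, cats,
        np.array([case_counts.get(c, 0) for c in cats]),
        np.array([ctrl_counts.get(c, 0) for c in cats]))


def bin_rare(table: AlleleCountTable,
             min_expected: float = 5.0) -> AlleleCountTable:
    """Collapse categories with expected count strictly below
    ``min_expected`` in either arm into the "binned" composite.

    Expected counts are the usual contingency expectations (row total x
    column total / grand total).  Membership is re-evaluated once after the
    merge (a single extra pass), since merging changes nothing for the
    surviving categories' totals only marginally.
    """
    t = table
    for _ in range(2):
        grand = t.case.sum() + t.control.sum()
        if grand == 0:
            raise ValueError("empty table")
        col = t.case + t.control
        exp_case = t.case.sum() * col / grand
        exp_ctrl = t.control.sum() * col / grand
        rare = [c for c, ec, eo in zip(t.categories, exp_case, exp_ctrl)
                if c != BINNED and (ec < min_expected or eo < min_expected)]
        if not rare:
            return t
        already = BINNED in t.categories
        t = t.merged(rare + ([BINNED] if already else []))
    return t


def locus_test(table: AlleleCountTable) -> tuple[float, int, float]:
    """Pearson chi-square of the 2 x k case/control-by-category table.
    Returns (statistic, df = k - 1, P)."""
    if table.k < 2:
        raise ValueError("need at least 2 categories")
    obs = np.vstack([table.case, table.control]).astype(float)
    grand = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    if (exp == 0).any():
        nz = exp[0] > 0
        obs, exp = obs[:, nz], exp[:, nz]
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.shape[1] - 1
    if obs.sum(axis=1).min() == 0:
        return 0.0, df, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def odds_ratio_from_freqs(f_case: float, f_control: float) -> float:
    """Allelic odds ratio from per-arm frequencies:
    (f_case/(1-f_case)) / (f_control/(1-f_control))."""
    if not (0 < f_case < 1 and 0 < f_control < 1):
        raise ValueError("frequencies must be in (0, 1)")
    return (f_case / (1 - f_case)) / (f_control / (1 - f_control))


def renormalized_freq(freq: float, removed_freq: float) -> float:
    """Frequency of a surviving category after removing a category of
    frequency ``removed_freq`` from the same arm: f / (1 - f_removed)."""
    if removed_freq >= 1:
        raise ValueError("cannot remove the whole arm")
    return freq / (1.0 - removed_freq)


def allele_test(table: AlleleCountTable, category: str,
                ) -> tuple[float, float, float]:
    """2 x 2 Pearson chi-square of one category against all others.

    Returns (chi2, P, OR).  The Haldane-Anscombe +0.5 correction is applied
    to all four cells only when some cell is zero.
    """
    i = table.index_of(category)
    a = float(table.case[i])               # case copies of the category
    b = float(table.case.sum() - a)
    c = float(table.control[i])
    d = float(table.control.sum() - c)
    obs = np.array([[a, b], [c, d]])
    grand = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    if (exp > 0).all():
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, 1))
    else:
        chi2, p = 0.0, 1.0
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    return chi2, p, float(or_)


@dataclass
class RpeStep:
    index: int
    excluded: tuple[str, ...]
    locus_p: float
    stats: pd.DataFrame  # category, freq_controls, freq_cases, p, or


@dataclass
class RpeTrace:
    locus: str | tuple
    steps: list[RpeStep] = field(default_factory=list)
    termination: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            df = s.stats.copy()
            df.insert(0, "step", s.index)
            df.insert(1, "excluded", ",".join(s.excluded) or "none")
            df.insert(2, "locus_p", s.locus_p)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")


def _step_stats(table: AlleleCountTable, test_alleles: bool) -> pd.DataFrame:
    fc = table.case_freqs()
    fo = table.control_freqs()
    rows = []
    for j, cat in enumerate(table.categories):
        if test_alleles:
            _, p, or_ = allele_test(table, cat)
        else:
            p, or_ = np.nan, np.nan
        rows.append((cat, fo[j], fc[j], p, or_))
    df = pd.DataFrame(rows, columns=["category", "freq_controls",
                                     "freq_cases", "p", "or"])
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def rpe_run(table: AlleleCountTable, config: AnalysisConfig | None = None,
            prebin: bool = True) -> RpeTrace:
    """Stepwise top-effect-allele removal.

    Loop: test the locus; while P_locus stays below the stop threshold,
    test every remaining category, record the step, remove the lowest-P
    category from both arms and continue.  The last recorded step is the
    first with P_locus at or above the threshold (its per-category tests
    are not performed, mirroring the locus-gated testing rule), or the step
    at which fewer than two categories remain.

    ``prebin`` applies the expected-count binning at entry; haplotype
    tables, binned on frequency instead, pass ``prebin=False``.
    """
    config = config or AnalysisConfig()
    if table.k < 2:
        raise ValueError("need at least 2 categories at step 0")
    if prebin:
        table = bin_rare(table, config.bin_min_expected)
    trace = RpeTrace(table.locus)
    excluded: tuple[str, ...] = ()
    step = 0
    while True:
        if table.k < 2:
            trace.termination = "exhausted"
            break
        _, _, locus_p = locus_test(table)
        significant = locus_p < config.rpe_locus_stop_p
        stats_df = _step_stats(table, test_alleles=significant)
        trace.steps.append(RpeStep(step, excluded, locus_p, stats_df))
        if not significant:
            trace.termination = "locus_nonsignificant"
            break
        removable = stats_df[stats_df["category"] != BINNED] \
            if not config.allow_binned_removal else stats_df
        if removable.empty:
            trace.termination = "exhausted"
            break
        top = removable.iloc[0]["category"]
        table = table.without(top)
        excluded = excluded + (top,)
        step += 1
    return trace


# ---------------------------------------------------------------------------
# EM haplotype estimation
# ---------------------------------------------------------------------------

def _compatible_pairs(genotype: tuple[tuple[str, str], ...]
                      ) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with an unphased multi-locus
    genotype (one (a1, a2) per locus)."""
    het = [i for i, (a, b) in enumerate(genotype) if a != b]
    if not het:
        h = tuple(a for a, _ in genotype)
        return [(h, h)]
    pairs = []
    # fix the first heterozygous locus to kill the mirror duplicates
    for flips in itertools.product([False, True], repeat=len(het) - 1):
        h1, h2 = [], []
        fi = 0
        for i, (a, b) in enumerate(genotype):
            if i not in het:
                h1.append(a)
                h2.append(a)
            elif i == het[0]:
                h1.append(a)
                h2.append(b)
            else:
                if flips[fi]:
                    h1.append(b)
                    h2.append(a)
                else:
                    h1.append(a)
                    h2.append(b)
                fi += 1
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


@dataclass
class EmResult:
    loci: tuple[str, ...]
    frequencies: dict[tuple, float]
    phases: dict[str, tuple[tuple, tuple]]  # subject -> most probable pair
    log_likelihood: float
    n_iter: int
    converged: bool


def em_haplotypes(hla: pd.DataFrame, loci: tuple[str, ...] | list[str],
                  tol: float = 1e-8, max_iter: int = 1000) -> EmResult:
    """EM haplotype-frequency estimation over unphased multi-locus HLA
    genotypes, with most-probable-phase hard assignment per subject.

    Only subjects with complete genotypes at every requested locus enter.
    The log-likelihood is non-decreasing across iterations; convergence is
    max |delta frequency| < ``tol`` or ``max_iter`` iterations.
    """
    loci = tuple(loci)
    wide: dict[str, dict[str, tuple[str, str]]] = {}
    for _, row in hla[hla["locus"].isin(loci)].iterrows():
        wide.setdefault(row["subject_id"], {})[row["locus"]] = (
            row["allele1"], row["allele2"])
    subjects = [s for s, g in wide.items() if all(l in g for l in loci)]
    if not subjects:
        raise ValueError(f"no subject complete at loci {loci}")
    genos = {s: tuple(tuple(sorted(wide[s][l])) for l in loci)
             for s in subjects}
    pair_lists = {s: _compatible_pairs(genos[s]) for s in subjects}
    hap_set = sorted({h for pl in pair_lists.values() for p in pl for h in p})
    freqs = {h: 1.0 / len(hap_set) for h in hap_set}
    n = len(subjects)
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        new = {h: 0.0 for h in hap_set}
        ll = 0.0
        for s in subjects:
            ws = []
            for h1, h2 in pair_lists[s]:
                w = freqs[h1] * freqs[h2]
                if h1 != h2:
                    w *= 2.0
                ws.append(w)
            tot = sum(ws)
            if tot <= 0:
                continue
            ll += np.log(tot)
            for (h1, h2), w in zip(pair_lists[s], ws):
                share = w / tot
                new[h1] += share
                new[h2] += share
        new = {h: v / (2.0 * n) for h, v in new.items()}
        delta = max(abs(new[h] - freqs[h]) for h in hap_set)
        assert ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), \
            "EM log-likelihood decreased"
        ll_prev = ll
        freqs = new
        if delta < tol:
            converged = True
            break
    phases = {}
    for s in subjects:
        best, best_w = None, -1.0
        for h1, h2 in pair_lists[s]:
            w = freqs[h1] * freqs[h2] * (2.0 if h1 != h2 else 1.0)
            if w > best_w:
                best, best_w = (h1, h2), w
        phases[s] = best
    return EmResult(loci, freqs, phases, float(ll_prev), it, converged)


def haplotype_counts(em: EmResult, pheno: PhenotypeTable, food: str,
                     ) -> AlleleCountTable:
    """Per-arm haplotype copy counts from hard-assigned phases."""
    case_ids = set(pheno.case_flags.index[pheno.case_flags[food]])
    ctrl_ids = set(pheno.is_control.index[pheno.is_control])
    case_counts: dict[tuple, int] = {}
    ctrl_counts: dict[tuple, int] = {}
    for sid, (h1, h2) in em.phases.items():
        if sid in case_ids:
            d = case_counts
        elif sid in ctrl_ids:
            d = ctrl_counts
        else:
            continue
        for h in (h1, h2):
            d[h] = d.get(h, 0) + 1
    cats = sorted(set(case_counts) | set(ctrl_counts))
    labels = ["~".join(h) for h in cats]
    return AlleleCountTable(
        tuple(em.loci), labels,
        np.array([case_counts.get(c, 0) for c in cats]),
        np.array([ctrl_counts.get(c, 0) for c in cats]))


def haplotype_rpe(hla: pd.DataFrame, loci: tuple[str, ...] | list[str],
                  pheno: PhenotypeTable, food: str,
                  config: AnalysisConfig | None = None) -> RpeTrace:
    """Stepwise RPE on estimated haplotypes: EM phase estimation (pooled
    over arms), hard-assigned counting, frequency binning (< 1% in either
    arm), then the standard stepwise removal."""
    config = config or AnalysisConfig()
    em = em_haplotypes(hla, loci)
    table = haplotype_counts(em, pheno, food)
    fc, fo = table.case_freqs(), table.control_freqs()
    rare = [c for c, a, b in zip(table.categories, fc, fo)
            if a < config.hap_bin_min_freq or b < config.hap_bin_min_freq]
    if rare and len(rare) < table.k:
        table = table.merged(rare)
    if table.k < 2:
        raise ValueError(
            "fewer than 2 haplotype categories after binning; the stepwise "
            "analysis needs at least two")
    return rpe_run(table, config, prebin=False)
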