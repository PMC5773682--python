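"""Variant and sample quality control.

Reproduces the genotyping-QC funnel of a two-sampleset GWAS: per-sampleset
variant filters (call rate, MAF, Hardy-Weinberg exact test, duplicate-pair
concordance), LD pruning, iterated PCA with automated outlier removal, and
method-of-moments IBD estimation (PI_HAT) for duplicate-sample detection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import GenotypeMatrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg P-value.

    Sums, conditional on the observed allele counts, the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed configuration (the classical mid-p-free exact test).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    # unnormalized probabilities over het counts of the right parity,
    # built by recurrence outward from the modal configuration
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    het, homr = mid, (rare - mid) // 2
    homc = n - het - homr
    while het > 1:
        probs[het - 2] = (probs[het] * het * (het - 1)
                          / (4.0 * (homr + 1) * (homc + 1)))
        het -= 2
        homr += 1
        homc += 1
    het, homr = mid, (rare - mid) // 2
    homc = n - het - homr
    while het <= rare - 2:
        probs[het + 2] = (probs[het] * 4.0 * homr * homc
                          / ((het + 2) * (het + 1)))
        het += 2
        homr -= 1
        homc -= 1
    target = probs[n_het]
    p = probs[probs <= target * (1 + 1e-12)].sum() / probs.sum()
    return float(min(p, 1.0))


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square Hardy-Weinberg test (config-selectable alternative)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass
class VariantQcReport:
    """Per-variant QC metrics per sampleset plus overall pass flags."""

    per_set: pd.DataFrame     # sampleset, id, call_rate, maf, hwe_p + flags
    concordance: pd.Series | None
    pass_overall: pd.Series   # indexed by variant id

    @property
    def passing_ids(self) -> list[str]:
        return list(self.pass_overall.index[self.pass_overall])


def _genotype_counts(dos: np.ndarray) -> tuple[int, int, int]:
    ok = dos[~np.isnan(dos)]
    g = np.rint(ok).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def variant_qc(geno: GenotypeMatrix, config: AnalysisConfig | None = None,
               duplicate_pairs: list[tuple[str, str]] | None = None,
               ) -> VariantQcReport:
    """Apply the four variant filters per sampleset.

    A variant must pass call-rate (strict >), MAF (>=), HWE (strict >) in
    *every* sampleset, and — when duplicate pairs are supplied —
    duplicate-pair concordance (strict >) overall.  A variant with zero
    non-missing genotypes fails call-rate rather than crashing.
    """
    config = config or AnalysisConfig()
    if geno.n_variants < 1 or geno.n_subjects < 2:
        raise ValueError("need at least 1 variant and 2 subjects")
    hwe = hwe_exact_p if config.hwe_test == "exact" else hwe_chisq_p
    sets = sorted(set(geno.sampleset))
    rows = []
    for ss in sets:
        sub = geno.dosages[geno.sampleset == ss]
        for j, vid in enumerate(geno.variants["id"]):
            dos = sub[:, j]
            n_ok = int((~np.isnan(dos)).sum())
            call_rate = n_ok / len(dos) if len(dos) else 0.0
            if n_ok == 0:
                maf = np.nan
                hwe_p = np.nan
            else:
                p = np.nanmean(dos) / 2.0
                maf = min(p, 1.0 - p)
                hwe_p = hwe(*_genotype_counts(dos))
            rows.append((ss, vid, call_rate, maf, hwe_p))
    per_set = pd.DataFrame(rows, columns=["sampleset", "id", "call_rate",
                                          "maf", "hwe_p"])
    per_set["pass_call_rate"] = per_set["call_rate"] > config.call_rate_min
    per_set["pass_maf"] = per_set["maf"] >= config.maf_min
    per_set["pass_hwe"] = per_set["hwe_p"] > config.hwe_p_min
    per_set["pass_set"] = (per_set["pass_call_rate"] & per_set["pass_maf"]
                           & per_set["pass_hwe"])

    conc = None
    conc_pass = pd.Series(True, index=list(geno.variants["id"]))
    if duplicate_pairs:
        conc = duplicate_concordance(geno, duplicate_pairs)
        conc_pass = conc > config.concordance_min
    overall = per_set.groupby("id", sort=False)["pass_set"].all()
    overall = overall.reindex(geno.variants["id"]) & conc_pass
    overall.name = "pass_overall"
    return VariantQcReport(per_set, conc, overall)


def duplicate_concordance(geno: GenotypeMatrix,
                          pairs: list[tuple[str, str]]) -> pd.Series:
    """Per-variant fraction of duplicate pairs with concordant calls.

    Pairs with a missing call at a variant are excluded from that variant's
    denominator; a variant with no informative pair gets NaN.
    """
    if not pairs:
        raise ValueError("need at least one duplicate pair")
    pos = {s: i for i, s in enumerate(geno.subjects)}
    agree = np.zeros(geno.n_variants)
    denom = np.zeros(geno.n_variants)
    for a, b in pairs:
        da, db = geno.dosages[pos[a]], geno.dosages[pos[b]]
        ok = ~np.isnan(da) & ~np.isnan(db)
        agree[ok] += (da[ok] == db[ok])
        denom[ok] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, agree / np.maximum(denom, 1), np.nan)
    return pd.Series(frac, index=list(geno.variants["id"]))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(geno: GenotypeMatrix, r2_threshold: float | None = None,
             window: int = 50, step: int = 5,
             config: AnalysisConfig | None = None) -> list[str]:
    """Greedy left-to-right LD pruning.

    A variant is dropped when its dosage r2 with any *retained* variant in
    the preceding ``window`` positions reaches the threshold.  Missing
    dosages are mean-imputed for the correlation (pruning is a screening
    heuristic, not an inferential step).
    """
    config = config or AnalysisConfig()
    thr = config.ld_prune_r2 if r2_threshold is None else r2_threshold
    if not 0.0 < thr <= 1.0:
        raise ValueError("r2 threshold must be in (0, 1]")
    X = geno.dosages.copy()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    retained: list[int] = []
    for j in range(geno.n_variants):
        if sd[j] == 0:
            continue  # constant variants carry no pruning information
        recent = [k for k in retained if j - k <= window]
        drop = False
        for k in recent:
            r = float(X[:, j] @ X[:, k] / (len(X) * sd[j] * sd[k]))
            if r * r >= thr - 1e-12:  # tolerance so exact copies hit thr=1
                drop = True
                break
        if not drop:
            retained.append(j)
    ids = list(geno.variants["id"])
    return [ids[j] for j in retained]


# ---------------------------------------------------------------------------
# PCA with iterated outlier removal
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    round_index: int
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    coordinates: pd.DataFrame     # subjects x PCs
    outlier_ids: list[str]


def _standardize(dosages: np.ndarray) -> np.ndarray:
    p = np.nanmean(dosages, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = dosages[:, keep].copy()
    p = p[keep]
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    X[np.isnan(X)] = 0.0  # mean imputation of missing calls
    return X


def pca_rounds(geno: GenotypeMatrix, config: AnalysisConfig | None = None,
               n_components: int = 10) -> list[PcaResult]:
    """Iterated PCA: decompose, flag subjects beyond k*SD on any top PC,
    remove them, repeat for the configured number of rounds.

    Genotypes are standardized per variant to mean 2p and SD sqrt(2p(1-p));
    constant variants are skipped.  PC signs are canonicalized so the
    largest-|loading| variant loads positively.  The final round's top
    ``config.n_pcs`` coordinates serve as regression covariates.
    """
    config = config or AnalysisConfig()
    if geno.n_subjects < 3:
        raise ValueError("need at least 3 subjects for PCA")
    current = geno
    results: list[PcaResult] = []
    for rnd in range(config.n_pca_rounds):
        X = _standardize(current.dosages)
        k = min(n_components, X.shape[0] - 1, X.shape[1])
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        # sign canonicalization on loadings
        for c in range(k):
            lead = np.argmax(np.abs(Vt[c]))
            if Vt[c, lead] < 0:
                Vt[c] *= -1
                U[:, c] *= -1
        scores = U * s
        eig = s ** 2 / max(X.shape[0] - 1, 1)
        total_var = (X ** 2).sum() / max(X.shape[0] - 1, 1)
        coords = pd.DataFrame(
            scores, index=list(current.subjects),
            columns=[f"PC{c + 1}" for c in range(k)])
        top = scores[:, :config.n_pcs]
        sd = top.std(axis=0)
        ctr = top.mean(axis=0)
        out_mask = (np.abs(top - ctr) > config.pca_outlier_sd * sd).any(axis=1)
        outliers = [s_ for s_, o in zip(current.subjects, out_mask) if o]
        results.append(PcaResult(rnd + 1, eig, eig / total_var, coords, outliers))
        if out_mask.all():
            raise ValueError(
                "every subject flagged as a PCA outlier; raise "
                "pca_outlier_sd or inspect the input")
        if out_mask.any() and rnd + 1 < config.n_pca_rounds:
            current = current.subset_subjects(~out_mask)
        elif rnd + 1 < config.n_pca_rounds:
            current = current  # no outliers; re-decompose same set
    return results


def pca_covariates(results: list[PcaResult],
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Top-PC covariate matrix from the final PCA round."""
    config = config or AnalysisConfig()
    final = results[-1]
    cols = [f"PC{c + 1}" for c in range(config.n_pcs)]
    return final.coordinates[cols]


# ---------------------------------------------------------------------------
# IBD / PI_HAT
# ---------------------------------------------------------------------------

@dataclass
class KinshipResult:
    pair: tuple[str, str]
    n_snps: int
    ibs0: int
    ibs1: int
    ibs2: int
    z0: float
    z1: float
    z2: float
    pi_hat: float


def ibd_pi_hat(geno: GenotypeMatrix,
               pairs: list[tuple[str, str]] | None = None,
               maf_min: float = 0.01) -> list[KinshipResult]:
    """Method-of-moments IBD-sharing estimates per subject pair.

    Uses IBS counts and sample allele frequencies to estimate Z0/Z1/Z2,
    projects them onto the probability simplex (clamping negatives and
    renormalizing), and reports PI_HAT = Z1/2 + Z2.  Restricted to variants
    with MAF >= ``maf_min``; per pair, only jointly non-missing variants
    contribute.
    """
    p_all = np.nanmean(geno.dosages, axis=0) / 2.0
    keep = np.minimum(p_all, 1 - p_all) >= maf_min
    D = geno.dosages[:, keep]
    p = p_all[keep]
    q = 1.0 - p
    e0 = 2 * p ** 2 * q ** 2
    e1_g0 = 4 * p ** 3 * q + 4 * p * q ** 3
    e2_g0 = p ** 4 + q ** 4 + 4 * p ** 2 * q ** 2
    e1_g1 = 2 * p * q
    e2_g1 = p ** 2 + q ** 2
    pos = {s: i for i, s in enumerate(geno.subjects)}
    if pairs is None:
        pairs = list(itertools.combinations(geno.subjects, 2))
    out = []
    for a, b in pairs:
        da, db = D[pos[a]], D[pos[b]]
        ok = ~np.isnan(da) & ~np.isnan(db)
        m = int(ok.sum())
        if m == 0:
            out.append(KinshipResult((a, b), 0, 0, 0, 0,
                                     np.nan, np.nan, np.nan, np.nan))
            continue
        diff = np.abs(da[ok] - db[ok])
        n0 = int((diff == 2).sum())
        n2 = int((diff == 0).sum())
        n1 = m - n0 - n2
        s0, s1g0, s2g0 = e0[ok].sum(), e1_g0[ok].sum(), e2_g0[ok].sum()
        s1g1, s2g1 = e1_g1[ok].sum(), e2_g1[ok].sum()
        z0 = n0 / s0 if s0 > 0 else 0.0
        z1 = (n1 - z0 * s1g0) / s1g1 if s1g1 > 0 else 0.0
        z2 = (n2 - z0 * s2g0 - z1 * s2g1) / m
        z = np.clip([z0, z1, z2], 0.0, None)
        z = z / z.sum() if z.sum() > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = float(np.clip(z[1] / 2 + z[2], 0.0, 1.0))
        out.append(KinshipResult((a, b), m, n0, n1, n2,
                                 float(z[0]), float(z[1]), float(z[2]), pi_hat))
    return out


def find_duplicates(results: list[KinshipResult],
                    config: AnalysisConfig | None = None,
                    ) -> tuple[list[tuple[str, str]], list[str]]:
    """Pairs with PI_HAT above the duplicate threshold, and the member of
    each pair flagged for removal (first by subject-id order)."""
    config = config or AnalysisConfig()
    dups = [r.pair for r in results
            if np.isfinite(r.pi_hat) and r.pi_hat > config.pi_hat_dup]
    removals = sorted({min(pair) for pair in dups})
    return dups, removals
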