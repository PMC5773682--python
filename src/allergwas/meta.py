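"""Bi-directional discovery-evaluation selection, BH FDR, inverse-variance
fixed-effects meta-analysis, and significance-tier calling.

The two samplesets serve simultaneously as discovery and evaluation arms: a
variant is a candidate if it reaches P <= 1e-4 in one arm and P < 0.05 with
Benjamini-Hochberg FDR < 0.2 in the other, in either direction (effect
direction concordance is not required).  Candidate variants are pooled by
inverse-variance weighting and tiered against the nominal (0.05 / effective
test count) and strong (nominal / number of foods) cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

Z_95 = 1.959964  # two-sided 95% normal quantile


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def or_ci_to_beta_se(odds_ratio: float, ci_low: float, ci_high: float,
                     ) -> tuple[float, float]:
    """Invert an "OR [95% CI]" display back to log-odds and standard error.

    beta = ln(OR); se = (ln hi - ln lo) / (2 * 1.959964).  A degenerate
    interval (lo == hi) yields se = 0, which downstream pooling rejects.
    """
    if not 0 < ci_low <= odds_ratio <= ci_high:
        raise ValueError(f"inconsistent OR/CI ({odds_ratio}, {ci_low}, {ci_high})")
    beta = float(np.log(odds_ratio))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2 * Z_95))
    return beta, se


def beta_se_to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    return (float(np.exp(beta)), float(np.exp(beta - Z_95 * se)),
            float(np.exp(beta + Z_95 * se)))


@dataclass
class PooledEstimate:
    beta: float
    se: float
    z: float
    p: float              # may underflow to 0 for extreme z
    neglog10_p: float     # always finite, computed on the log scale
    or_: float
    ci_low: float
    ci_high: float


def ivw_pool(betas: list[float] | np.ndarray,
             ses: list[float] | np.ndarray) -> PooledEstimate:
    """Fixed-effects inverse-variance pooling of per-set estimates.

    w_i = 1/se_i^2; pooled beta = sum(w b)/sum(w); pooled se = sqrt(1/sum w).
    The two-sided normal P is computed on the log scale so extreme signals
    keep a finite -log10(P).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two estimates to pool")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s ** 2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    log_p = np.log(2.0) + stats.norm.logsf(abs(z))
    neglog10 = float(-log_p / np.log(10.0))
    p = float(np.exp(log_p)) if log_p > -700 else 0.0
    or_, lo, hi = beta_se_to_or_ci(beta, se)
    return PooledEstimate(beta, se, float(z), p, neglog10, or_, lo, hi)


@dataclass
class MetaRecord:
    variant_id: str
    effect_allele: str
    set_betas: dict[str, float]
    set_ses: dict[str, float]
    set_ps: dict[str, float]
    pooled: PooledEstimate
    candidate: bool = False
    discovery_direction: str = ""
    tier: str = "none"


def harmonize_effect_alleles(set_a: pd.DataFrame,
                             set_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two per-set summary tables on variant id, flipping set-B betas
    whose effect/other alleles are swapped relative to set A.  Variants with
    irreconcilable alleles raise with the offending ids listed."""
    m = set_a.merge(set_b, on="id", suffixes=("_a", "_b"))
    same = ((m["effect_allele_a"] == m["effect_allele_b"])
            & (m["other_allele_a"] == m["other_allele_b"]))
    flipped = ((m["effect_allele_a"] == m["other_allele_b"])
               & (m["other_allele_a"] == m["effect_allele_b"]))
    bad = ~(same | flipped)
    if bad.any():
        raise ValueError("allele mismatch for variant(s): "
                         + ", ".join(m.loc[bad, "id"].tolist()))
    m.loc[flipped, "beta_b"] = -m.loc[flipped, "beta_b"]
    m.loc[flipped, ["effect_allele_b", "other_allele_b"]] = \
        m.loc[flipped, ["other_allele_b", "effect_allele_b"]].to_numpy()
    return m


def discovery_evaluation(set_a: pd.DataFrame, set_b: pd.DataFrame,
                         config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Bi-directional candidate selection over a shared variant universe.

    Input frames need columns ``id`` and ``p``.  Per direction, evaluation
    FDR is computed over the evaluation-arm P-values of the variants that
    passed discovery in the other arm (config-switchable to genome-wide).
    Returns the candidate table with the direction(s) of discovery.
    """
    config = config or AnalysisConfig()
    a = set_a.set_index("id")["p"]
    b = set_b.set_index("id")["p"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]

    def one_direction(disc: pd.Series, ev: pd.Series) -> pd.Index:
        hits = disc.index[disc <= config.p_discovery_max]
        if len(hits) == 0:
            return pd.Index([])
        if config.fdr_universe == "direction":
            fdr = pd.Series(bh_fdr(ev.loc[hits].to_numpy()), index=hits)
        else:
            fdr = pd.Series(bh_fdr(ev.to_numpy()), index=ev.index).loc[hits]
        ok = (ev.loc[hits] < config.p_eval_max) & (fdr < config.fdr_eval_max)
        return hits[ok]

    ab = one_direction(a, b)
    ba = one_direction(b, a)
    rows = []
    for vid in shared:
        in_ab, in_ba = vid in ab, vid in ba
        if in_ab or in_ba:
            direction = ("both" if in_ab and in_ba
                         else ("A->B" if in_ab else "B->A"))
            rows.append((vid, float(a[vid]), float(b[vid]), direction))
    return pd.DataFrame(rows, columns=["id", "p_a", "p_b", "direction"])


def call_tiers(p_meta: float, is_candidate: bool,
               config: AnalysisConfig | None = None) -> str:
    """Significance tier for one pooled P-value.  Tiers apply only to
    discovery-evaluation survivors; non-candidates stay "none"."""
    config = config or AnalysisConfig()
    if not is_candidate:
        return "none"
    if p_meta < config.p_strong:
        return "strong"
    if p_meta < config.p_nominal:
        return "nominal"
    return "candidate"


def meta_analyze(set_a: pd.DataFrame, set_b: pd.DataFrame,
                 config: AnalysisConfig | None = None,
                 labels: tuple[str, str] = ("LL01", "LL02"),
                 ) -> list[MetaRecord]:
    """Full selection + pooling: harmonize alleles, pick candidates
    bi-directionally, IVW-pool every shared variant, call tiers."""
    config = config or AnalysisConfig()
    merged = harmonize_effect_alleles(set_a, set_b)
    # variants without a converged fit in both sets cannot be pooled
    ok = (np.isfinite(merged["se_a"]) & (merged["se_a"] > 0)
          & np.isfinite(merged["se_b"]) & (merged["se_b"] > 0))
    merged = merged[ok]
    cands = discovery_evaluation(set_a[["id", "p"]], set_b[["id", "p"]], config)
    cand_dir = dict(zip(cands["id"], cands["direction"]))
    out = []
    for _, r in merged.iterrows():
        pooled = ivw_pool([r["beta_a"], r["beta_b"]], [r["se_a"], r["se_b"]])
        is_cand = r["id"] in cand_dir
        out.append(MetaRecord(
            variant_id=r["id"],
            effect_allele=r["effect_allele_a"],
            set_betas={labels[0]: r["beta_a"], labels[1]: r["beta_b"]},
            set_ses={labels[0]: r["se_a"], labels[1]: r["se_b"]},
            set_ps={labels[0]: r["p_a"], labels[1]: r["p_b"]},
            pooled=pooled,
            candidate=is_cand,
            discovery_direction=cand_dir.get(r["id"], ""),
            tier=call_tiers(pooled.p, is_cand, config),
        ))
    return out
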