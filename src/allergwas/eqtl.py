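"""GWAS-eQTL overlap via the relative signal strength (RSS) statistic.

For a SNP-gene pair, RSS = -log10(P_SNP) / -log10(P_gene.min) measures how
close the SNP's expression signal is to the strongest eQTL signal for that
gene within a database (per tissue for the GTEx-like dialect, then
maximized across tissues).  Candidate genes for a GWAS signal are those
with at least one SNP in moderate LD with the top GWAS SNP that is a
reasonably strong eQTL in *both* databases:

    (r2 > 0.5 or r2_equiv > 0.5) & RSS_HGVD > 0.2 & max.RSS_GTEx > 0.2

A wider listing table keeps pairs passing either database (OR rule).
HGVD-dialect records are prefiltered to R2 > 0.1 (variance explained in
the expression association), and GTEx-dialect listing output is restricted
to genes whose best SNP is associated in at least 10 tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig

P_FLOOR = 1e-320


def rss(p_snp: float, p_gene_min: float) -> float:
    """Relative signal strength: ratio of -log10 P-values."""
    if not (p_snp > 0 and p_gene_min > 0):
        raise ValueError("P-values must be > 0")
    num = -np.log10(max(p_snp, P_FLOOR))
    den = -np.log10(max(p_gene_min, P_FLOOR))
    if den == 0:
        raise ValueError("gene minimum P of 1 gives an undefined RSS")
    return float(num / den)


def hgvd_prefilter(records: pd.DataFrame,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Keep HGVD-dialect records with r2_expl strictly above the threshold."""
    config = config or AnalysisConfig()
    if "r2_expl" not in records.columns:
        raise ValueError("not an HGVD-dialect table (no r2_expl column)")
    return records[records["r2_expl"] > config.hgvd_r2_min].reset_index(drop=True)


def gtex_tissue_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Tissue count per SNP-gene pair in a GTEx-dialect table."""
    return (records.groupby(["snp", "gene"])["tissue"].nunique()
            .rename("n_tissues").reset_index())


def gtex_tissue_count_filter(records: pd.DataFrame, min_tissues: int = 10,
                             ) -> pd.DataFrame:
    """Drop genes whose best (most widely associated) SNP appears in fewer
    than ``min_tissues`` tissues.  Applied to listing output only."""
    if records.empty:
        return records.copy()
    counts = gtex_tissue_counts(records)
    best = counts.groupby("gene")["n_tissues"].max()
    keep = set(best.index[best >= min_tissues])
    return records[records["gene"].isin(keep)].reset_index(drop=True)


def gtex_rss(records: pd.DataFrame) -> pd.DataFrame:
    """max.RSS per SNP-gene pair: per-tissue RSS against the gene-tissue
    minimum P, maximized across tissues; with the pair's tissue count."""
    df = records.copy()
    df["p_min"] = df.groupby(["gene", "tissue"])["p"].transform("min")
    df["rss"] = [rss(p, pm) for p, pm in zip(df["p"], df["p_min"])]
    out = (df.groupby(["snp", "gene"])
           .agg(max_rss_gtex=("rss", "max"), n_tissues=("tissue", "nunique"))
           .reset_index())
    return out


def hgvd_rss(records: pd.DataFrame,
             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """RSS per SNP-gene pair in the (prefiltered) HGVD-dialect table."""
    df = hgvd_prefilter(records, config)
    if df.empty:
        return pd.DataFrame(columns=["snp", "gene", "rss_hgvd"])
    df = df.copy()
    df["p_min"] = df.groupby("gene")["p"].transform("min")
    df["rss_hgvd"] = [rss(p, pm) for p, pm in zip(df["p"], df["p_min"])]
    return df[["snp", "gene", "rss_hgvd"]]


def candidate_genes(ld_set: pd.DataFrame, gtex: pd.DataFrame,
                    hgvd: pd.DataFrame,
                    config: AnalysisConfig | None = None,
                    ) -> tuple[set[str], pd.DataFrame]:
    """Dual-database candidate-gene filter around one GWAS signal.

    ``ld_set`` is the LD-classified table (columns test_id, moderate) for
    the top GWAS SNP.  Returns (candidate gene set — the AND rule — and the
    listing table of pairs passing the OR rule, tissue-count filtered).
    """
    config = config or AnalysisConfig()
    mod_snps = set(ld_set.loc[ld_set["moderate"], "test_id"])
    # RSS denominators (per-gene minimum P) come from the full database;
    # only afterwards are pairs restricted to the moderate-LD SNP set
    g = gtex_rss(gtex) if len(gtex) else \
        pd.DataFrame(columns=["snp", "gene", "max_rss_gtex", "n_tissues"])
    h = hgvd_rss(hgvd, config) if len(hgvd) else \
        pd.DataFrame(columns=["snp", "gene", "rss_hgvd"])
    g = g[g["snp"].isin(mod_snps)]
    h = h[h["snp"].isin(mod_snps)]
    merged = g.merge(h, on=["snp", "gene"], how="outer")
    merged["pass_gtex"] = merged["max_rss_gtex"] > config.rss_min
    merged["pass_hgvd"] = merged["rss_hgvd"] > config.rss_min
    merged[["pass_gtex", "pass_hgvd"]] = \
        merged[["pass_gtex", "pass_hgvd"]].fillna(False)
    merged["candidate_pair"] = merged["pass_gtex"] & merged["pass_hgvd"]
    candidates = set(merged.loc[merged["candidate_pair"], "gene"])
    listing = merged[merged["pass_gtex"] | merged["pass_hgvd"]].copy()
    # tissue-count confidence filter applies to the listing only
    ok_genes = set(gtex_tissue_count_filter(
        gtex, config.gtex_min_tissues)["gene"]) if len(gtex) else set()
    listing = listing[listing["gene"].isin(ok_genes | set(h["gene"]))]
    listing = listing.reset_index(drop=True)
    return candidates, listing
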