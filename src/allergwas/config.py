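"""Run configuration: every threshold the pipeline applies, in one place.

The defaults are the analysis cut-offs of the study design this package
models (variant QC, duplicate detection, discovery-evaluation selection,
meta-analysis significance tiers, HLA call-threshold filtering, RPE stop
rule, LD classes, eQTL filters).  All are overridable per run, and a flat
``key<TAB>value`` text file round-trips the full configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AnalysisConfig:
    # variant QC (applied per sampleset; a variant must pass in both)
    call_rate_min: float = 0.99        # strict >: ">99% call-rate"
    maf_min: float = 0.01              # inclusive >=
    hwe_p_min: float = 1e-6            # strict >
    concordance_min: float = 0.90      # strict >, duplicate-pair concordance
    # LD pruning / PCA / IBD
    ld_prune_r2: float = 0.2           # drop if r2 >= threshold with retained
    ld_prune_window: int = 50          # variants per sliding window
    ld_prune_step: int = 5
    n_pca_rounds: int = 3
    pca_outlier_sd: float = 6.0        # k*SD outlier rule on top PCs
    n_pcs: int = 2                     # covariate PCs from the final round
    pi_hat_dup: float = 0.8            # strict >: duplicate pair call
    # discovery-evaluation selection
    p_discovery_max: float = 1e-4      # inclusive <=
    p_eval_max: float = 0.05           # strict <
    fdr_eval_max: float = 0.2          # strict <
    fdr_universe: str = "direction"    # "direction" or "genomewide"
    # significance tiers
    effective_test_count: int = 411_521
    n_foods_tested: int = 27
    p_nominal: float = 1.21e-7         # printed value of 0.05/411521
    p_strong: float = 4.4e-9           # printed value of p_nominal/27
    min_cases_per_set: int = 100       # strict >: eligibility per food
    # RPE / HLA
    rpe_locus_stop_p: float = 0.05     # stop when locus P >= this
    bin_min_expected: float = 5.0      # strict <: expected-count binning
    hap_bin_min_freq: float = 0.01     # strict <: haplotype frequency binning
    allow_binned_removal: bool = False
    hwe_test: str = "exact"            # "exact" or "chisq"
    ct_min: float = 0.5                # strict >: HLA call-threshold filter
    # LD classes
    ld_moderate: float = 0.5
    ld_high: float = 0.8
    ld_class_rule: str = "or"          # "or" (r2 OR r2_equiv) or "equiv_only"
    # eQTL overlap
    rss_min: float = 0.2               # strict >
    hgvd_r2_min: float = 0.1           # strict >
    gtex_min_tissues: int = 10         # inclusive >=

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "concordance_min",
                     "ld_prune_r2", "pi_hat_dup", "hap_bin_min_freq",
                     "ld_moderate", "ld_high", "rss_min", "hgvd_r2_min",
                     "ct_min", "fdr_eval_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in ("hwe_p_min", "p_discovery_max", "p_eval_max",
                     "p_nominal", "p_strong", "rpe_locus_stop_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v!r} outside (0, 1]")
        if self.p_strong > self.p_nominal:
            raise ValueError("p_strong must be <= p_nominal")
        if self.fdr_universe not in ("direction", "genomewide"):
            raise ValueError(f"unknown fdr_universe {self.fdr_universe!r}")
        if self.ld_class_rule not in ("or", "equiv_only"):
            raise ValueError(f"unknown ld_class_rule {self.ld_class_rule!r}")
        if self.hwe_test not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_test {self.hwe_test!r}")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}\t{getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                key, value = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"malformed config line {lineno}: {raw!r}") from exc
            if key not in types:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value in ("True", "true", "1")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
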