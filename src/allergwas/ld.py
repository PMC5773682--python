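"""Linkage-disequilibrium metrics: dosage-correlation r2 and the
conditional LD-equivalent statistic r2_equiv.

r2_equiv quantifies how much of a tested variant B's association signal is
explained by conditioning on a regional top SNP A, on the -log10(P) scale:
with Z = -log10(P), r2_equiv = (Z_B - Z_B|A) / Z_A.  It is 1 when B *is* A
(the collinear conditional test has P = 1 by convention), 0 when
conditioning changes nothing, and may be negative when conditioning
sharpens the signal (it is deliberately not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import GenotypeMatrix

P_FLOOR = 1e-320


def dosage_r2(geno: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation of alternate-allele dosages over
    pairwise-complete subjects; NaN when either vector is constant."""
    d1, d2 = geno.dosage_of(v1), geno.dosage_of(v2)
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    if ok.sum() < 2:
        raise ValueError("need at least 2 jointly called subjects")
    a, b = d1[ok], d2[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r2_equiv(p_top: float, p_b: float, p_b_cond: float) -> float:
    """(Z_B - Z_B|A) / Z_A with Z = -log10(P); P = 0 inputs are floored at
    1e-320 before taking logs."""
    for name, p in (("p_top", p_top), ("p_b", p_b), ("p_b_cond", p_b_cond)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    z_a = -np.log10(max(p_top, P_FLOOR))
    z_b = -np.log10(max(p_b, P_FLOOR))
    z_bc = -np.log10(max(p_b_cond, P_FLOOR))
    if z_a == 0:
        raise ValueError("top-SNP P-value of 1 gives an undefined r2_equiv")
    return float((z_b - z_bc) / z_a)


@dataclass
class LdEquivResult:
    top_id: str
    test_id: str
    r2_dosage: float
    r2_equiv_: float


def ld_table(geno: GenotypeMatrix, top_id: str,
             unconditional: pd.DataFrame,
             conditional: pd.DataFrame) -> pd.DataFrame:
    """Per-variant LD metrics around one top SNP.

    ``unconditional``/``conditional`` are summary frames with columns
    ``id`` and ``p`` from the plain and the top-SNP-conditioned GWAS.
    """
    p_un = unconditional.set_index("id")["p"]
    p_cn = conditional.set_index("id")["p"]
    p_top = float(p_un[top_id])
    rows = []
    for vid in p_un.index:
        if vid not in p_cn.index:
            continue
        pb, pbc = float(p_un[vid]), float(p_cn[vid])
        re_ = (np.nan if not (np.isfinite(pb) and np.isfinite(pbc))
               else r2_equiv(p_top, pb, pbc))
        rows.append((top_id, vid, dosage_r2(geno, top_id, vid), re_))
    return pd.DataFrame(rows, columns=["top_id", "test_id", "r2", "r2_equiv"])


def ld_class(results: pd.DataFrame,
             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Classify variants as in moderate / high LD with the top SNP.

    Default rule ("or"): moderate if r2 > 0.5 OR r2_equiv > 0.5, high if
    either exceeds 0.8 (the rule used for the eQTL overlap); the
    "equiv_only" rule uses r2_equiv alone.  High LD implies moderate.
    """
    config = config or AnalysisConfig()
    out = results.copy()
    r2 = out["r2"].fillna(-np.inf)
    re_ = out["r2_equiv"].fillna(-np.inf)
    if config.ld_class_rule == "or":
        mod = (r2 > config.ld_moderate) | (re_ > config.ld_moderate)
        high = (r2 > config.ld_high) | (re_ > config.ld_high)
    else:
        mod = re_ > config.ld_moderate
        high = re_ > config.ld_high
    out["moderate"] = mod | high
    out["high"] = high
    return out
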