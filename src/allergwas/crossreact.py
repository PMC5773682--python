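"""Cross-reactivity proportion matrix over the questionnaire foods.

M[x][y] is the proportion of subjects reacting to food x who also react to
food y — an asymmetric conditional proportion (the denominator is the row
food's reactor count), so M[shrimp][crab] and M[crab][shrimp] generally
differ.  The heatmap ordering clusters foods by average-linkage
hierarchical clustering of the symmetrized matrix, which groups fruit,
nut and shellfish blocks when the underlying liabilities are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .assoc import PhenotypeTable


@dataclass
class CrossReactMatrix:
    foods: list[str]
    proportions: pd.DataFrame   # M[x][y], rows = x
    counts: pd.DataFrame        # joint reactor counts
    n_reactors: pd.Series       # per-food reactor counts

    def write_tsv(self, path: str | Path,
                  counts_path: str | Path | None = None) -> None:
        self.proportions.to_csv(path, sep="\t", float_format="%.6g")
        if counts_path is not None:
            self.counts.to_csv(counts_path, sep="\t")


def cross_react(pheno: PhenotypeTable) -> CrossReactMatrix:
    """Compute the asymmetric cross-reactivity matrix from case flags.

    Foods with zero reactors get an all-missing row (no NaN propagation
    into other rows); the diagonal is 1 wherever any subject reacts.
    """
    flags = pheno.case_flags.astype(int)
    foods = list(flags.columns)
    joint = flags.T @ flags                      # co-reactor counts
    n = pd.Series(np.diag(joint), index=foods)
    with np.errstate(divide="ignore", invalid="ignore"):
        props = joint.div(n, axis=0)
    props[n == 0] = np.nan                       # empty-row foods
    return CrossReactMatrix(foods, props.astype(float), joint, n)


def order_for_heatmap(matrix: CrossReactMatrix) -> list[str]:
    """Food ordering for plotting: average-linkage clustering on the
    symmetrized similarity max(M, M^T); deterministic, ties broken by the
    input (label) order of the foods."""
    M = matrix.proportions.fillna(0.0).to_numpy()
    sim = np.maximum(M, M.T)
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if len(matrix.foods) < 3:
        return list(matrix.foods)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return [matrix.foods[i] for i in leaves]
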