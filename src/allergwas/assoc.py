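"""Case/control phenotype construction and additive logistic GWAS.

Case definition: a subject is a case for a food if the questionnaire
response to that food is mild or severe; controls are subjects with "none"
for *every* food, shared across all per-food analyses.  A food enters the
GWAS only with strictly more than ``min_cases_per_set`` cases in each
sampleset.

The association model is a per-variant logistic regression of case status
on alternate-allele dosage with optional covariates (top PCs), fitted by
Newton/IRLS with complete-case handling of missing dosages.  Conditional
analysis adds a conditioning variant's dosage as a covariate; a tested
variant collinear with the conditioning variant is reported with Wald P = 1
by convention, so the conditional LD-equivalent statistic of a variant with
itself is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import AnalysisConfig
from .io import GenotypeMatrix, RESPONSES

P_FLOOR = 1e-320  # numerical floor for -log10 arithmetic downstream


@dataclass
class PhenotypeTable:
    """Wide per-subject food responses with derived case/control codings."""

    responses: pd.DataFrame     # subjects x foods, values none/mild/severe
    sampleset: pd.Series        # per subject
    case_flags: pd.DataFrame    # subjects x foods, bool
    is_control: pd.Series       # bool, all-none subjects
    eligible_foods: list[str]

    @property
    def subjects(self) -> list[str]:
        return list(self.responses.index)


def build_phenotypes(questionnaire: pd.DataFrame,
                     config: AnalysisConfig | None = None) -> PhenotypeTable:
    """Derive case flags, the shared control set, and eligible foods from a
    long-form questionnaire (subject_id, sampleset, food, response)."""
    config = config or AnalysisConfig()
    bad = ~questionnaire["response"].isin(RESPONSES)
    if bad.any():
        raise ValueError(f"unknown responses: "
                         f"{sorted(questionnaire.loc[bad, 'response'].unique())}")
    wide = questionnaire.pivot(index="subject_id", columns="food",
                               values="response")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"responses missing for food(s) {missing}")
    ss = (questionnaire.drop_duplicates("subject_id")
          .set_index("subject_id")["sampleset"].reindex(wide.index))
    case = wide.isin(["mild", "severe"])
    control = (wide == "none").all(axis=1)
    eligible = []
    for food in wide.columns:
        counts = case[food].groupby(ss).sum()
        if len(counts) > 0 and (counts > config.min_cases_per_set).all():
            eligible.append(food)
    return PhenotypeTable(wide, ss, case, control, eligible)


# ---------------------------------------------------------------------------
# Newton / IRLS logistic fit
# ---------------------------------------------------------------------------

def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 25,
                 tol: float = 1e-8, beta_cap: float = 20.0,
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit.

    Returns (beta, se, converged).  Non-convergence within ``max_iter``
    iterations, a singular information matrix, or any |beta| beyond
    ``beta_cap`` (the quasi-separation convention) yields converged=False.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    if not converged or np.abs(beta).max() > beta_cap:
        return beta, np.full(k, np.nan), False
    eta = np.clip(X @ beta, -30, 30)
    w = expit(eta) * (1 - expit(eta))
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, np.full(k, np.nan), False
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        return beta, se, False
    return beta, se, True


def wald_p(z: float) -> float:
    """Two-sided normal tail probability, floored for -log10 arithmetic."""
    return float(max(2.0 * stats.norm.sf(abs(z)), P_FLOOR))


@dataclass
class AssocRecord:
    variant_id: str
    effect_allele: str
    other_allele: str
    n_cases: int
    n_controls: int
    beta: float
    se: float
    p: float
    converged: bool
    sampleset: str = ""


@dataclass
class GwasRun:
    food: str
    sampleset: str
    records: list[AssocRecord]
    lambda_gc: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def lambda_gc(p_values: np.ndarray | list[float]) -> float:
    """Genomic-control inflation factor: median association chi-square over
    its null expectation (the 1-df chi-square median)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 P-values for lambda_GC")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))


def logistic_gwas(geno: GenotypeMatrix, pheno: PhenotypeTable, food: str,
                  covariates: pd.DataFrame | None = None,
                  sampleset: str | None = None,
                  condition_on: str | None = None) -> GwasRun:
    """Per-variant additive logistic GWAS of one food.

    Subjects are the food's cases plus the shared controls (optionally
    restricted to one sampleset); covariate columns are aligned by subject
    id.  Per variant the fit is complete-case in the dosage.  Lambda_GC is
    attached when at least 100 converged tests are available.
    """
    sel = pheno.case_flags[food] | pheno.is_control
    if sampleset is not None:
        sel = sel & (pheno.sampleset == sampleset)
    selected = set(sel.index[sel])
    ids = [s for s in geno.subjects if s in selected]
    if not ids:
        raise ValueError("no analysable subjects")
    sub = geno.subset_subjects(ids)
    y = pheno.case_flags[food].reindex(ids).to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError(f"zero cases for {food!r}")
    if y.sum() == len(y):
        raise ValueError(f"zero controls for {food!r}")
    cov = None
    if covariates is not None:
        cov = covariates.reindex(ids).to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("covariates missing for some subjects")
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(ids)), cov])) \
                < cov.shape[1] + 1:
            raise ValueError("covariate matrix not full rank")
    cond = None
    if condition_on is not None:
        cond = sub.dosage_of(condition_on)

    records = []
    for j, vrow in sub.variants.iterrows():
        dos = sub.dosages[:, j]
        ok = ~np.isnan(dos)
        if cond is not None:
            ok &= ~np.isnan(cond)
        d = dos[ok]
        yy = y[ok]
        n_ca, n_co = int(yy.sum()), int((1 - yy).sum())
        rec = AssocRecord(vrow["id"], vrow["alt"], vrow["ref"], n_ca, n_co,
                          np.nan, np.nan, np.nan, False,
                          sampleset or "ALL")
        if d.size == 0 or np.ptp(d) == 0 or n_ca == 0 or n_co == 0:
            records.append(rec)
            continue
        cols = [np.ones(ok.sum()), d]
        if cov is not None:
            cols.append(cov[ok])
        if cond is not None:
            c = cond[ok]
            same = (vrow["id"] == condition_on)
            if not same and np.ptp(c) > 0:
                r = np.corrcoef(d, c)[0, 1]
                same = abs(r) > 1 - 1e-10
            if same:
                # testing the conditioning variant (or a perfect proxy):
                # the conditional signal is nil by convention
                rec.beta, rec.se, rec.p, rec.converged = 0.0, np.nan, 1.0, True
                records.append(rec)
                continue
            cols.append(c)
        X = np.column_stack(cols)
        beta, se, conv = fit_logistic(X, yy)
        if conv:
            rec.beta = float(beta[1])
            rec.se = float(se[1])
            rec.p = wald_p(beta[1] / se[1])
            rec.converged = True
        records.append(rec)

    run = GwasRun(food, sampleset or "ALL", records)
    ps = [r.p for r in records if r.converged and np.isfinite(r.p)]
    if len(ps) >= 100:
        run.lambda_gc = lambda_gc(np.array(ps))
    return run


def conditional_gwas(geno: GenotypeMatrix, pheno: PhenotypeTable, food: str,
                     condition_on: str,
                     covariates: pd.DataFrame | None = None,
                     sampleset: str | None = None) -> GwasRun:
    """The same model with the conditioning variant's dosage as an extra
    covariate (used for the conditional LD-equivalent statistic)."""
    if condition_on not in set(geno.variants["id"]):
        raise KeyError(f"conditioning variant {condition_on!r} not present")
    return logistic_gwas(geno, pheno, food, covariates=covariates,
                         sampleset=sampleset, condition_on=condition_on)


def summary_frame(run: GwasRun, geno: GenotypeMatrix) -> pd.DataFrame:
    """Assemble the writable summary-statistics table for one GWAS run."""
    df = run.to_frame().rename(columns={"variant_id": "id",
                                        "other_allele": "other_allele"})
    meta = geno.variants[["chrom", "pos", "id"]]
    out = meta.merge(df, on="id")
    return out[["chrom", "pos", "id", "effect_allele", "other_allele",
                "n_cases", "n_controls", "beta", "se", "p"]]
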