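"""Truth-annotated synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
samplesets of diploid subjects built from a founder-haplotype pool (so SNPs
carry within-block LD and tag SNPs can sit in configurable LD with HLA risk
alleles), multi-allelic HLA genotypes drawn from realistic Japanese control
spectra with DRB1~DQB1 haplotype coupling, per-food case status from an
additive logistic liability with group-correlated (cross-reactivity)
components, a mild/severe split among cases, byte-identical duplicate
sample pairs, a small admixed-outlier fraction, and uniform genotype
missingness.  All randomness flows from the single integer seed in
:class:`SimConfig`; the same config yields bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import datasets
from .io import GenotypeMatrix


@dataclass(frozen=True)
class PlantedEffect:
    """A causal effect planted on one food.

    ``kind`` is one of ``"snp"`` (target = variant id), ``"hla"``
    (target = (locus, allele)) or ``"haplotype"`` (target = tuple of
    (locus, allele) pairs carried on one founder haplotype).
    """

    food: str
    kind: str
    target: tuple | str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "hla", "haplotype"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be > 0")

    @property
    def beta(self) -> float:
        return float(np.log(self.odds_ratio))


def _default_effects() -> tuple[PlantedEffect, ...]:
    return (
        PlantedEffect("peach", "hla", ("DRB1", "09:01"), 1.67),
        PlantedEffect("shrimp", "haplotype",
                      (("DRB1", "04:05"), ("DQB1", "04:01")), 1.99),
    )


def _normalized(freqs: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    out = {}
    for locus, spec in freqs.items():
        vals = np.array(list(spec.values()), dtype=float)
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError(f"{locus}: allele frequencies must lie in (0, 1)")
        total = vals.sum()
        if not 0.9 <= total <= 1.1:
            raise ValueError(f"{locus}: frequencies sum to {total:.3f}, not ~1")
        out[locus] = {a: v / total for a, v in zip(spec, vals)}
    return out


@dataclass
class SimConfig:
    """Study-design constants for the generator.

    Defaults reflect the emulated study conditions: two samplesets of
    5751/5628 women, 27 questionnaire foods, 329 duplicate samples, 19
    admixed outliers, control HLA spectra, and the two planted HLA-region
    risk effects (peach DRB1*09:01 OR 1.67; shrimp DRB1*04:05-DQB1*04:01
    haplotype OR 1.99) each tagged by a SNP at r2 ~ 0.8.  Desk-scale runs
    override the sizes.
    """

    n_subjects_per_set: tuple[int, int] = (5751, 5628)
    n_snps: int = 500
    ld_block_size: int = 10
    n_founder_haplotypes: int = 200
    n_block_ancestors: int = 4
    block_mutation_rate: float = 0.02
    hla_allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 datasets.CONTROL_HLA_FREQS.items()})
    hla_coupling: float = 0.85
    planted_effects: tuple[PlantedEffect, ...] = field(
        default_factory=_default_effects)
    tag_r2: float = 0.8
    baseline_prevalence: float | dict[str, float] = 0.03
    group_liability_sd: float = 1.0
    severe_fraction: float = 0.2
    n_duplicate_pairs: int = 329
    n_admixed: int = 19
    admix_freq_shift: float = 0.3
    missing_rate: float = 0.002
    low_ct_fraction: float = 0.02
    foods: tuple[str, ...] = datasets.FOODS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        self.hla_allele_freqs = _normalized(self.hla_allele_freqs)
        for eff in self.planted_effects:
            if eff.food not in self.foods:
                raise ValueError(f"planted effect on unknown food {eff.food!r}")

    def prevalence(self, food: str) -> float:
        if isinstance(self.baseline_prevalence, dict):
            return self.baseline_prevalence.get(food, 0.03)
        return float(self.baseline_prevalence)


@dataclass
class FounderPool:
    """Pool of founder haplotypes: one SNP allele vector + one HLA allele
    per locus per founder, plus per-effect tag-SNP indices."""

    snp_haplotypes: np.ndarray           # (n_founders, n_snps) in {0, 1}
    hla: dict[str, np.ndarray]           # locus -> allele code per founder
    blocks: np.ndarray                   # block index per SNP
    tag_snp: dict[int, int]              # planted-effect index -> SNP column

    @property
    def n_founders(self) -> int:
        return self.snp_haplotypes.shape[0]

    def carries(self, effect: PlantedEffect) -> np.ndarray:
        """Boolean per founder: does the haplotype carry the risk target?"""
        if effect.kind == "hla":
            locus, allele = effect.target
            return self.hla[locus] == allele
        if effect.kind == "haplotype":
            mask = np.ones(self.n_founders, dtype=bool)
            for locus, allele in effect.target:
                mask &= self.hla[locus] == allele
            return mask
        raise ValueError("SNP effects have no founder carrier indicator")


class TagR2Unattainable(ValueError):
    pass


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> FounderPool:
    """Draw the founder haplotype pool.

    SNP alleles within an LD block are copies (with a small mutation rate)
    of one of a few ancestral block haplotypes, so within-block dosage LD is
    high and between-block LD is ~0.  For each planted HLA/haplotype effect
    a tag SNP is rewritten so its founder-pool correlation with the risk
    indicator matches ``sqrt(config.tag_r2)``; an unattainable target (risk
    target absent or fixed in the pool) raises :class:`TagR2Unattainable`.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_f, n_snps = config.n_founder_haplotypes, config.n_snps
    blocks = np.arange(n_snps) // config.ld_block_size
    haplos = np.zeros((n_f, n_snps), dtype=np.int8)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        freqs = rng.uniform(0.1, 0.9, size=len(cols))
        ancestors = (rng.random((config.n_block_ancestors, len(cols))) <
                     freqs).astype(np.int8)
        choice = rng.integers(0, config.n_block_ancestors, size=n_f)
        block_h = ancestors[choice]
        flip = rng.random(block_h.shape) < config.block_mutation_rate
        haplos[:, cols] = block_h ^ flip

    hla: dict[str, np.ndarray] = {}
    spectra = config.hla_allele_freqs
    if "DRB1" in spectra:
        drb1_alleles = np.array(list(spectra["DRB1"]))
        drb1_p = np.array(list(spectra["DRB1"].values()))
        hla["DRB1"] = drb1_alleles[rng.choice(len(drb1_alleles), n_f, p=drb1_p)]
    if "DQB1" in spectra:
        dqb1_alleles = np.array(list(spectra["DQB1"]))
        dqb1_p = np.array(list(spectra["DQB1"].values()))
        indep = dqb1_alleles[rng.choice(len(dqb1_alleles), n_f, p=dqb1_p)]
        if "DRB1" in hla:
            partner = np.array([
                datasets.DRB1_DQB1_PARTNERS.get(a, "") for a in hla["DRB1"]])
            use_partner = ((rng.random(n_f) < config.hla_coupling)
                           & np.isin(partner, dqb1_alleles))
            hla["DQB1"] = np.where(use_partner, partner, indep)
        else:
            hla["DQB1"] = indep
    for locus in spectra:
        if locus in hla:
            continue
        alleles = np.array(list(spectra[locus]))
        p = np.array(list(spectra[locus].values()))
        hla[locus] = alleles[rng.choice(len(alleles), n_f, p=p)]

    pool = FounderPool(haplos, hla, blocks, {})
    for i, eff in enumerate(config.planted_effects):
        if eff.kind == "snp":
            continue
        carrier = pool.carries(eff)
        n1 = int(carrier.sum())
        if n1 == 0 or n1 == n_f:
            raise TagR2Unattainable(
                f"tag r2={config.tag_r2} unattainable for {eff.target}: risk "
                f"target {'absent from' if n1 == 0 else 'fixed in'} the "
                f"founder pool (size {n_f}); enlarge the pool or the "
                f"target's frequency")
        col = int((i + 1) * config.ld_block_size - 1) % n_snps
        f = n1 / n_f
        rho = float(np.sqrt(config.tag_r2))
        a = f + rho * (1 - f)      # P(tag=1 | carrier)
        b = f * (1 - rho)          # P(tag=1 | non-carrier)
        tag = np.zeros(n_f, dtype=np.int8)
        car_idx = np.flatnonzero(carrier)
        non_idx = np.flatnonzero(~carrier)
        k1 = int(round(a * len(car_idx)))
        k0 = int(round(b * len(non_idx)))
        tag[rng.permutation(car_idx)[:k1]] = 1
        tag[rng.permutation(non_idx)[:k0]] = 1
        if config.tag_r2 >= 1.0:
            tag = carrier.astype(np.int8)
        achieved = np.corrcoef(tag, carrier.astype(float))[0, 1] ** 2
        if abs(achieved - config.tag_r2) > 0.15:
            raise TagR2Unattainable(
                f"founder pool of size {n_f} too small to realize tag "
                f"r2={config.tag_r2} for {eff.target} (achieved {achieved:.3f})")
        haplos[:, col] = tag
        pool.tag_snp[i] = col
    return pool


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, reloadable bit-identically."""

    seed: int
    causal_effects: list[dict]           # food / kind / target / beta / tag snp
    founder_assignment: np.ndarray       # (n_base_subjects, 2)
    group_liability: pd.DataFrame        # subjects x food groups
    admixed_ids: list[str]
    duplicate_pairs: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "causal_effects": self.causal_effects,
            "founder_assignment": self.founder_assignment.tolist(),
            "group_liability": {
                "index": list(self.group_liability.index),
                "columns": list(self.group_liability.columns),
                "values": self.group_liability.to_numpy().tolist(),
            },
            "admixed_ids": self.admixed_ids,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        obj = json.loads(Path(path).read_text())
        gl = obj["group_liability"]
        return cls(
            seed=obj["seed"],
            causal_effects=obj["causal_effects"],
            founder_assignment=np.array(obj["founder_assignment"], dtype=int),
            group_liability=pd.DataFrame(gl["values"], index=gl["index"],
                                         columns=gl["columns"]),
            admixed_ids=obj["admixed_ids"],
            duplicate_pairs=[tuple(p) for p in obj["duplicate_pairs"]],
        )

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, CohortTruth):
            return NotImplemented
        return (self.seed == other.seed
                and self.causal_effects == other.causal_effects
                and np.array_equal(self.founder_assignment,
                                   other.founder_assignment)
                and np.allclose(self.group_liability, other.group_liability)
                and list(self.group_liability.index) == list(other.group_liability.index)
                and self.admixed_ids == other.admixed_ids
                and self.duplicate_pairs == other.duplicate_pairs)


@dataclass
class SimulatedCohort:
    geno: GenotypeMatrix
    hla: pd.DataFrame            # subject_id, locus, allele1, allele2, ct
    questionnaire: pd.DataFrame  # long: subject_id, sampleset, food, response
    truth: CohortTruth
    founders: FounderPool


def _jsonable(obj):
    """Recursively turn tuples into lists so truth survives JSON identically."""
    if isinstance(obj, (tuple, list)):
        return [_jsonable(x) for x in obj]
    return obj


def _target_dosage(eff: PlantedEffect, pool: FounderPool,
                   assign: np.ndarray, dosages: np.ndarray,
                   snp_ids: list[str]) -> np.ndarray:
    if eff.kind == "snp":
        j = snp_ids.index(eff.target)  # type: ignore[arg-type]
        return dosages[:, j].astype(float)
    carrier = pool.carries(eff).astype(np.int8)
    return (carrier[assign[:, 0]] + carrier[assign[:, 1]]).astype(float)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort (see module docstring).

    Raises ``ValueError`` if a planted food ends with fewer than two cases.
    """
    rng = np.random.default_rng(config.seed)
    pool = simulate_founders(config, rng)
    n1, n2 = config.n_subjects_per_set
    n = n1 + n2
    subjects = [f"S{i + 1:06d}" for i in range(n)]
    sampleset = np.array(["LL01"] * n1 + ["LL02"] * n2, dtype=object)
    assign = rng.integers(0, pool.n_founders, size=(n, 2))
    dosages = (pool.snp_haplotypes[assign[:, 0]]
               + pool.snp_haplotypes[assign[:, 1]]).astype(float)
    snp_ids = [f"snp{j + 1:05d}" for j in range(config.n_snps)]

    # admixed outliers: genotypes redrawn from a coherently shifted spectrum
    admixed_idx = (rng.choice(n, size=config.n_admixed, replace=False)
                   if config.n_admixed else np.array([], dtype=int))
    if config.n_admixed:
        maf = pool.snp_haplotypes.mean(axis=0)
        shift_dir = np.where(maf < 0.5, 1.0, -1.0)
        p_adm = np.clip(maf + config.admix_freq_shift * shift_dir, 0.02, 0.98)
        dosages[admixed_idx] = rng.binomial(
            2, p_adm, size=(config.n_admixed, config.n_snps)).astype(float)

    # per-subject per-group shared liability (cross-reactivity driver)
    groups = list(datasets.FOOD_GROUPS)
    liab = rng.normal(0.0, config.group_liability_sd, size=(n, len(groups)))
    liability = pd.DataFrame(liab, index=subjects, columns=groups)

    # per-food case status from the additive logistic model
    effects_by_food: dict[str, list[tuple[PlantedEffect, np.ndarray]]] = {}
    for eff in config.planted_effects:
        dose = _target_dosage(eff, pool, assign, dosages, snp_ids)
        effects_by_food.setdefault(eff.food, []).append((eff, dose))
    responses = {}
    for food in config.foods:
        eta = logit(config.prevalence(food)) + liab[:, groups.index(
            datasets.FOOD_TO_GROUP.get(food, groups[0]))]
        for eff, dose in effects_by_food.get(food, []):
            eta = eta + eff.beta * dose
        case = rng.random(n) < expit(eta)
        severe = case & (rng.random(n) < config.severe_fraction)
        resp = np.where(severe, "severe", np.where(case, "mild", "none"))
        responses[food] = resp
        if food in effects_by_food and case.sum() < 2:
            raise ValueError(
                f"planted food {food!r} produced only {int(case.sum())} "
                f"case(s); increase n_subjects_per_set or its prevalence")

    # duplicate pairs: byte-identical genotype/HLA/response copies
    dup_pairs: list[tuple[str, str]] = []
    if config.n_duplicate_pairs:
        non_admixed = np.setdiff1d(np.arange(n), admixed_idx)
        src = rng.choice(non_admixed, size=config.n_duplicate_pairs,
                         replace=False)
        dup_ids = [f"{subjects[i]}D" for i in src]
        dup_pairs = [(subjects[i], d) for i, d in zip(src, dup_ids)]
        subjects = subjects + dup_ids
        sampleset = np.concatenate([sampleset, sampleset[src]])
        dosages = np.vstack([dosages, dosages[src]])
        assign = np.vstack([assign, assign[src]])
        for food in config.foods:
            responses[food] = np.concatenate(
                [responses[food], responses[food][src]])

    n_all = len(subjects)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    variants = pd.DataFrame({
        "chrom": "6",
        "pos": np.arange(1, config.n_snps + 1) * 1000,
        "id": snp_ids, "ref": "A", "alt": "G",
    })
    geno = GenotypeMatrix(subjects, variants, dosages, sampleset)

    hla_rows = []
    ct = np.ones((n_all, len(pool.hla)))
    low = rng.random(ct.shape) < config.low_ct_fraction
    ct[low] = rng.uniform(0.3, 1.0, size=int(low.sum()))
    for li, locus in enumerate(pool.hla):
        a1 = pool.hla[locus][assign[:, 0]]
        a2 = pool.hla[locus][assign[:, 1]]
        for i in range(n_all):
            hla_rows.append((subjects[i], locus, a1[i], a2[i],
                             round(float(ct[i, li]), 6)))
    hla = pd.DataFrame(hla_rows, columns=["subject_id", "locus",
                                          "allele1", "allele2", "ct"])

    quest = pd.DataFrame({
        "subject_id": np.repeat(subjects, len(config.foods)),
        "sampleset": np.repeat(sampleset, len(config.foods)),
        "food": np.tile(config.foods, n_all),
        "response": np.concatenate(
            [[responses[f][i] for f in config.foods] for i in range(n_all)]),
    })

    truth = CohortTruth(
        seed=config.seed,
        causal_effects=[{
            "food": eff.food, "kind": eff.kind,
            "target": _jsonable(eff.target),
            "beta": eff.beta,
            "tag_snp": (snp_ids[pool.tag_snp[i]] if i in pool.tag_snp else None),
        } for i, eff in enumerate(config.planted_effects)],
        founder_assignment=assign[:n],
        group_liability=liability,
        admixed_ids=[subjects[i] for i in admixed_idx],
        duplicate_pairs=dup_pairs,
    )
    return SimulatedCohort(geno, hla, quest, truth, pool)


# ---------------------------------------------------------------------------
# eQTL summary tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignatedEqtl:
    """A SNP-gene pair given true eQTL signal in the synthetic tables."""

    snp: str
    gene: str
    gtex_neglog10_p: float = 12.0
    hgvd_neglog10_p: float = 10.0
    hgvd_r2: float = 0.3
    n_tissues: int = 12


def simulate_eqtl_tables(config: SimConfig, assoc_snps: list[str],
                         designated: tuple[DesignatedEqtl, ...] = (),
                         n_null_genes: int = 0, n_tissues: int = 15,
                         hgvd_coverage: float = 0.25,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a GTEx-like and an HGVD-like eQTL summary table.

    Designated pairs get the configured small P-values (the per-gene minimum
    by construction) and HGVD ``r2_expl`` above/below the 0.1 prefilter as
    configured; non-designated pairs are null: P ~ Uniform(0.01, 1) and
    ``r2_expl`` ~ Uniform(0, 0.1), i.e. below the variance-explained filter,
    as expected for SNPs with no real expression effect.  HGVD covers only
    ``hgvd_coverage`` of positions (designated SNPs always present),
    mirroring its sparser array backbone.
    """
    if not assoc_snps:
        raise ValueError("assoc_snps is empty: nothing to tabulate")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = [d.gene for d in designated]
    genes += [f"NULLGENE{k + 1}" for k in range(n_null_genes)]
    if not genes:
        genes = ["NULLGENE1"]
    des_map = {(d.snp, d.gene): d for d in designated}

    gtex_rows = []
    for gene in genes:
        for snp in assoc_snps:
            d = des_map.get((snp, gene))
            k_tis = d.n_tissues if d else int(rng.integers(3, n_tissues + 1))
            tissues = [f"tissue{t + 1:02d}" for t in range(k_tis)]
            for tis in tissues:
                p = (10.0 ** (-d.gtex_neglog10_p) if d
                     else float(rng.uniform(0.01, 1.0)))
                gtex_rows.append((snp, gene, tis, p))
    gtex = pd.DataFrame(gtex_rows, columns=["snp", "gene", "tissue", "p"])

    hgvd_rows = []
    covered = {s for s in assoc_snps if rng.random() < hgvd_coverage}
    covered |= {d.snp for d in designated}
    for gene in genes:
        for snp in assoc_snps:
            if snp not in covered:
                continue
            d = des_map.get((snp, gene))
            if d:
                hgvd_rows.append((snp, gene, 10.0 ** (-d.hgvd_neglog10_p),
                                  d.hgvd_r2))
            else:
                hgvd_rows.append((snp, gene, float(rng.uniform(0.01, 1.0)),
                                  float(rng.uniform(0.0, 0.1))))
    hgvd = pd.DataFrame(hgvd_rows, columns=["snp", "gene", "p", "r2_expl"])
    return gtex, hgvd
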