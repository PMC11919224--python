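"""Synthetic cohorts and pedigrees under a liability-threshold disease model.

The generator emulates the statistical structure the analysis assumes: a
panel of ~167 GWAS risk variants (26 flagged HLA-like, one of them a large
effect with OR 2.9; the rest with ORs on the 1.05-1.6 scale of non-HLA
effects), a population in Hardy-Weinberg and linkage equilibrium whose
disease arises when liability — the weighted genetic score plus independent
Gaussian environment — exceeds the threshold set by prevalence, and
multigeneration pedigrees produced by Mendelian gene dropping with optional
monozygotic twin pairs, ascertained by rejection sampling for a minimum
number of affected members.

Defaults are calibrated so the case-control score distribution discriminates
with AUC ~ 0.75 (``liability_h2_polygenic = 0.18`` at ``disease_prevalence =
0.05``); see the methods note for the calibration argument and for what this
generator deliberately does not model (linkage disequilibrium, rare
family-specific variants, shared environment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_io import DosageMatrix, PedigreeRecord
from .errors import ValidationError
from .gwas_panel import RiskPanel

__all__ = [
    "SimulationConfig",
    "PopulationSim",
    "FamilySim",
    "simulate_panel",
    "simulate_population",
    "simulate_case_control_cohort",
    "ascertain_case_control",
    "make_family_template",
    "simulate_family",
    "ascertain_multicase_families",
]

# ordered non-ambiguous SNP allele pairs (risk, other)
_SNP_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
              ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generator."""

    n_variants: int = 167
    n_hla: int = 26
    large_effect_or: float = 2.9
    large_effect_freq: float = 0.15
    or_range: tuple[float, float] = (1.05, 1.6)
    freq_range: tuple[float, float] = (0.1, 0.9)
    disease_prevalence: float = 0.05
    liability_h2_polygenic: float = 0.18
    n_cases: int = 500
    n_controls: int = 900
    n_families: int = 3
    min_affected_per_family: int = 3
    max_family_attempts: int = 20000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ValidationError("disease_prevalence must be in (0, 1)")
        if not 0.0 <= self.liability_h2_polygenic <= 1.0:
            raise ValidationError("liability_h2_polygenic must be in [0, 1]")
        if self.or_range[0] <= 0 or self.large_effect_or <= 0:
            raise ValidationError("odds ratios must be > 0")
        if not (0.0 < self.freq_range[0] <= self.freq_range[1] < 1.0):
            raise ValidationError("allele frequencies must lie in (0, 1)")
        if self.n_hla > self.n_variants:
            raise ValidationError("n_hla cannot exceed n_variants")


@dataclass
class PopulationSim:
    """Unascertained population sample with liabilities and affection."""

    dosages: DosageMatrix
    score: np.ndarray
    liability: np.ndarray
    affected: np.ndarray
    sex: np.ndarray  # 0 = male, 1 = female
    threshold: float


@dataclass
class FamilySim:
    """One gene-dropped family."""

    dosages: DosageMatrix
    pedigree: list[PedigreeRecord]
    score: np.ndarray
    liability: np.ndarray
    affected: np.ndarray
    n_affected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_affected = int(self.affected.sum())


def simulate_panel(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RiskPanel, np.ndarray]:
    """Draw a risk panel and its risk-allele frequencies.

    Exactly one HLA-like variant carries ``large_effect_or``; the remaining
    ORs are uniform on ``or_range``.  HLA-like variants are placed on
    chromosome 6 (29.4-33.2 Mb); the rest are spread over the autosomes.
    Variants are emitted non-ambiguous so a panel built from this output
    survives harmonization unchanged.
    """
    m = config.n_variants
    ors = rng.uniform(*config.or_range, size=m)
    freqs = rng.uniform(*config.freq_range, size=m)
    if m > 0:
        ors[0] = config.large_effect_or
        freqs[0] = config.large_effect_freq
    pair_idx = rng.integers(0, len(_SNP_PAIRS), size=m)
    rows = []
    hla_pos = np.sort(rng.integers(29_400_000, 33_200_000, size=config.n_hla))
    for i in range(m):
        hla = i < config.n_hla
        risk, other = _SNP_PAIRS[pair_idx[i]]
        if hla:
            chrom, pos = "6", int(hla_pos[i])
            vid = f"hla{i + 1:03d}"
        else:
            chrom = str((i % 22) + 1)
            pos = int(1_000_000 + 10_000 * i)
            vid = f"snp{i + 1:04d}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": chrom,
                "pos": pos,
                "risk_allele": risk,
                "other_allele": other,
                "odds_ratio": float(ors[i]),
                "weight": math.log(float(ors[i])),
                "hla": hla,
            }
        )
    panel = RiskPanel(pd.DataFrame(rows), provenance={"n_summary": m, "simulated": 1})
    return panel, freqs


def _score_moments(panel: RiskPanel, freqs: np.ndarray) -> tuple[float, float]:
    w = panel.weights
    f = np.asarray(freqs, dtype=float)
    mean = float(np.sum(2.0 * f * w))
    var = float(np.sum(w ** 2 * 2.0 * f * (1.0 - f)))
    return mean, var


def liability_model(
    panel: RiskPanel, freqs: np.ndarray, config: SimulationConfig
) -> tuple[float, float]:
    """Environmental SD and affection threshold implied by the config.

    sigma_env is set so the genetic score explains ``liability_h2_polygenic``
    of liability variance; the threshold is the normal-approximation quantile
    of liability at 1 - prevalence.
    """
    mean_s, var_s = _score_moments(panel, freqs)
    h2 = config.liability_h2_polygenic
    if h2 <= 0:
        raise ValidationError("liability_model undefined at h2 = 0")
    sigma_env = math.sqrt(var_s * (1.0 - h2) / h2)
    sd_l = math.sqrt(var_s + sigma_env ** 2)
    from scipy.stats import norm

    threshold = mean_s + norm.ppf(1.0 - config.disease_prevalence) * sd_l
    return sigma_env, threshold


def _affection(score: np.ndarray, config: SimulationConfig,
               sigma_env: float, threshold: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    liability = score + rng.normal(0.0, sigma_env, size=score.size)
    return liability, liability > threshold


def simulate_population(
    panel: RiskPanel,
    freqs: np.ndarray,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    id_prefix: str = "ind",
) -> PopulationSim:
    """Hardy-Weinberg, linkage-equilibrium population of size ``n``.

    Genotypes are Binomial(2, freq) per variant; liability is the genetic
    score plus Gaussian environment.  With ``liability_h2_polygenic = 0``
    affection is independent Bernoulli(prevalence) — the null model.
    """
    m = len(panel)
    G = rng.binomial(2, np.asarray(freqs, float), size=(n, m)).astype(float)
    score = G @ panel.weights
    if config.liability_h2_polygenic > 0:
        sigma_env, threshold = liability_model(panel, freqs, config)
        liability, affected = _affection(score, config, sigma_env, threshold, rng)
    else:
        liability = rng.normal(0.0, 1.0, size=n)
        threshold = float(
            np.sqrt(2.0) * _erfinv(1.0 - 2.0 * config.disease_prevalence)
        )
        affected = liability > threshold
    ids = [f"{id_prefix}{i + 1:06d}" for i in range(n)]
    alleles = {
        r.variant_id: (r.risk_allele, r.other_allele)
        for r in panel.variants.itertuples(index=False)
    }
    positions = (
        {r.variant_id: (str(r.chrom), int(r.pos))
         for r in panel.variants.itertuples(index=False)}
        if "chrom" in panel.variants.columns
        else None
    )
    dmat = DosageMatrix(ids, panel.variant_ids, G, alleles, positions)
    sex = rng.integers(0, 2, size=n)
    return PopulationSim(dmat, score, liability, affected, sex, threshold)


def _erfinv(x: float) -> float:
    from scipy.special import erfinv

    return float(erfinv(x))


def ascertain_case_control(
    population: PopulationSim,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Sample cases and controls without replacement from a population.

    Returns the genotype subset and a label frame (individual_id, group,
    sex).
    """
    case_idx = np.flatnonzero(population.affected)
    ctrl_idx = np.flatnonzero(~population.affected)
    if case_idx.size < n_cases or ctrl_idx.size < n_controls:
        raise ValidationError(
            f"population has {case_idx.size} cases / {ctrl_idx.size} controls; "
            f"requested {n_cases} / {n_controls}"
        )
    pick_cases = rng.choice(case_idx, size=n_cases, replace=False)
    pick_ctrls = rng.choice(ctrl_idx, size=n_controls, replace=False)
    order = np.concatenate([pick_cases, pick_ctrls])
    ids = [population.dosages.sample_ids[i] for i in order]
    labels = pd.DataFrame(
        {
            "individual_id": ids,
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "sex": population.sex[order],
        }
    )
    return population.dosages.select_samples(ids), labels


def simulate_case_control_cohort(
    panel: RiskPanel,
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_batches: int = 30,
) -> tuple[DosageMatrix, pd.DataFrame, PopulationSim]:
    """Simulate until the requested case/control counts are available.

    Batches are sized from prevalence with head-room; exceeding
    ``max_batches`` raises.  Returns the cohort genotypes, labels and the
    last pooled population (for reference moments).
    """
    K = config.disease_prevalence
    batch = int(max(2000, 1.5 * config.n_cases / K))
    pools: list[PopulationSim] = []
    n_aff = n_unaff = 0
    for b in range(max_batches):
        pop = simulate_population(panel, freqs, batch, config, rng,
                                  id_prefix=f"b{b}i")
        pools.append(pop)
        n_aff += int(pop.affected.sum())
        n_unaff += int((~pop.affected).sum())
        if n_aff >= config.n_cases and n_unaff >= config.n_controls:
            break
    else:
        raise ValidationError(
            f"could not reach {config.n_cases} cases in {max_batches} batches "
            f"at prevalence {K}"
        )
    merged = _merge_populations(pools, panel)
    cohort, labels = ascertain_case_control(
        merged, config.n_cases, config.n_controls, rng
    )
    return cohort, labels, merged


def _merge_populations(pools: Sequence[PopulationSim], panel: RiskPanel) -> PopulationSim:
    if len(pools) == 1:
        return pools[0]
    first = pools[0]
    ids = [s for p in pools for s in p.dosages.sample_ids]
    dmat = DosageMatrix(
        ids,
        panel.variant_ids,
        np.vstack([p.dosages.dosages for p in pools]),
        first.dosages.alleles,
        first.dosages.positions,
    )
    return PopulationSim(
        dmat,
        np.concatenate([p.score for p in pools]),
        np.concatenate([p.liability for p in pools]),
        np.concatenate([p.affected for p in pools]),
        np.concatenate([p.sex for p in pools]),
        first.threshold,
    )


# ---------------------------------------------------------------------------
# Families

def make_family_template(
    family_id: str,
    rng: np.random.Generator,
    n_offspring: int | None = None,
    mz_pair: bool | None = None,
    n_grandchildren: int = 2,
) -> list[PedigreeRecord]:
    """Three-generation family skeleton: two founders, 5-7 offspring, a
    married-in spouse with children, and optionally an MZ twin pair among
    the offspring (drawn with probability 1/3 when unspecified)."""
    if n_offspring is None:
        n_offspring = int(rng.integers(5, 8))
    if mz_pair is None:
        mz_pair = bool(rng.random() < 1.0 / 3.0)
    f = f"{family_id}-f"
    m = f"{family_id}-m"
    recs = [
        PedigreeRecord(family_id, f, sex="male"),
        PedigreeRecord(family_id, m, sex="female"),
    ]
    offspring_sex = ["male" if rng.random() < 0.5 else "female"
                     for _ in range(n_offspring)]
    if mz_pair:
        offspring_sex[1] = offspring_sex[0]
    for i in range(n_offspring):
        recs.append(
            PedigreeRecord(
                family_id,
                f"{family_id}-o{i + 1}",
                father_id=f,
                mother_id=m,
                sex=offspring_sex[i],
                mz_group="mz1" if (mz_pair and i < 2) else None,
            )
        )
    # third generation through the last offspring and a married-in spouse
    parent = f"{family_id}-o{n_offspring}"
    spouse_sex = "female" if offspring_sex[-1] == "male" else "male"
    spouse = f"{family_id}-s1"
    recs.append(PedigreeRecord(family_id, spouse, sex=spouse_sex))
    father, mother = (parent, spouse) if offspring_sex[-1] == "male" else (spouse, parent)
    for i in range(n_grandchildren):
        recs.append(
            PedigreeRecord(
                family_id,
                f"{family_id}-g{i + 1}",
                father_id=father,
                mother_id=mother,
                sex="male" if rng.random() < 0.5 else "female",
            )
        )
    return recs


def simulate_family(
    panel: RiskPanel,
    freqs: np.ndarray,
    template: Sequence[PedigreeRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> FamilySim:
    """Gene-drop genotypes down a pedigree template and assign affection.

    Founders draw haplotypes from population frequencies; each non-founder
    receives one allele per parent, chosen uniformly and independently per
    variant; MZ co-twins copy genotypes exactly.  Liability and the
    affection threshold are the same as in the population simulation, with
    independent environment per individual (including within MZ pairs).
    """
    m = len(panel)
    f = np.asarray(freqs, dtype=float)
    by_id = {r.individual_id: r for r in template}
    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    mz_rep: dict[str, str] = {}
    groups: dict[str, str] = {}
    for r in template:
        if r.mz_group is not None:
            key = f"{r.family_id}:{r.mz_group}"
            groups.setdefault(key, r.individual_id)
            mz_rep[r.individual_id] = groups[key]

    def drop(iid: str) -> tuple[np.ndarray, np.ndarray]:
        if iid in hap:
            return hap[iid]
        rep = mz_rep.get(iid)
        if rep is not None and rep != iid:
            hap[iid] = drop(rep)
            return hap[iid]
        r = by_id[iid]
        if r.is_founder:
            h = (
                (rng.random(m) < f).astype(np.int8),
                (rng.random(m) < f).astype(np.int8),
            )
        else:
            if r.father_id not in by_id or r.mother_id not in by_id:
                raise ValidationError(
                    f"template references missing parent for {iid}"
                )
            fh = drop(r.father_id)
            mh = drop(r.mother_id)
            h = (
                np.where(rng.random(m) < 0.5, fh[0], fh[1]),
                np.where(rng.random(m) < 0.5, mh[0], mh[1]),
            )
        hap[iid] = h
        return h

    ids = [r.individual_id for r in template]
    G = np.array([drop(i)[0] + drop(i)[1] for i in ids], dtype=float)
    score = G @ panel.weights
    sigma_env, threshold = liability_model(panel, freqs, config)
    liability, affected = _affection(score, config, sigma_env, threshold, rng)
    pedigree = [
        replace(by_id[iid], affection="affected" if affected[i] else "unaffected")
        for i, iid in enumerate(ids)
    ]
    alleles = {
        r.variant_id: (r.risk_allele, r.other_allele)
        for r in panel.variants.itertuples(index=False)
    }
    positions = (
        {r.variant_id: (str(r.chrom), int(r.pos))
         for r in panel.variants.itertuples(index=False)}
        if "chrom" in panel.variants.columns
        else None
    )
    dmat = DosageMatrix(ids, panel.variant_ids, G, alleles, positions)
    return FamilySim(dmat, pedigree, score, liability, affected)


def ascertain_multicase_families(
    panel: RiskPanel,
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    template_fn: Callable[[str, np.random.Generator], Sequence[PedigreeRecord]] | None = None,
) -> tuple[list[FamilySim], int]:
    """Rejection-sample families until ``n_families`` meet the criterion.

    A family is accepted when it has at least ``min_affected_per_family``
    affected members.  Returns the accepted families and the total number of
    attempts (the empirical ascertainment rate is n_families / attempts).
    """
    if config.min_affected_per_family < 0:
        raise ValidationError("min_affected_per_family must be >= 0")
    tfn = template_fn or make_family_template
    accepted: list[FamilySim] = []
    attempts = 0
    while len(accepted) < config.n_families:
        if attempts >= config.max_family_attempts:
            raise ValidationError(
                f"exhausted {config.max_family_attempts} attempts with "
                f"{len(accepted)}/{config.n_families} families accepted; "
                f"min_affected={config.min_affected_per_family}, "
                f"prevalence={config.disease_prevalence}"
            )
        attempts += 1
        fam_id = f"F{len(accepted) + 1}"
        template = tfn(fam_id, rng)
        fam = simulate_family(panel, freqs, template, config, rng)
        if fam.n_affected >= config.min_affected_per_family:
            accepted.append(fam)
    return accepted, attempts
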