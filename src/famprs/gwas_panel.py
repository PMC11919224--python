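"""Harmonize GWAS summary records with genotyped datasets into a risk panel.

A polygenic score can only be computed over variants that (a) are genotyped
or imputed in *every* dataset being scored, (b) have a strand-resolvable
allele pair, and (c) can be oriented so that dosages count the GWAS risk
allele.  ``build_panel`` applies those three rules in order — intersection,
ambiguous-SNP exclusion (A/T and C/G pairs, whose strand cannot be inferred
from the alleles alone), and per-dataset orientation — and records how many
variants each rule removed.

Weights are natural-log odds ratios.  Records with OR < 1 are re-oriented to
the opposite allele (OR -> 1/OR), so every panel weight is non-negative and
the score is a sum of risk-increasing contributions; dosage complementation
for swapped variants is handled by :func:`align_dosages`.

HLA-allele pseudo-markers (non-nucleotide allele tokens such as ``P``/``A``
for presence/absence of a classical four-digit allele) take part in
intersection and orientation but bypass the nucleotide strand logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import NUCLEOTIDES, DosageMatrix, GwasSummaryRecord
from .errors import FormatError, ValidationError

__all__ = [
    "Orientation",
    "RiskPanel",
    "is_ambiguous",
    "harmonize_variant",
    "build_panel",
    "align_dosages",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Orientation(Enum):
    """How observed dosages relate to the GWAS risk allele.

    Observed allele pairs are ordered ``(counted, other)`` — the first allele
    is the one the dosage counts (ALT for a VCF source).
    """

    MATCH = "match"              # counted allele IS the risk allele
    SWAP = "swap"                # counted allele is the other allele: use 2 - d
    STRAND_FLIP = "strand_flip"  # risk allele on the opposite strand: use d
    STRAND_FLIP_SWAP = "strand_flip_swap"  # opposite strand and swapped: 2 - d
    FAIL = "fail"                # alleles irreconcilable; variant dropped

    @property
    def swapped(self) -> bool:
        return self in (Orientation.SWAP, Orientation.STRAND_FLIP_SWAP)


def is_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True iff the unordered pair is A/T or C/G (strand-ambiguous)."""
    if allele_a not in NUCLEOTIDES or allele_b not in NUCLEOTIDES:
        raise ValidationError(
            f"non-nucleotide allele in SNP ambiguity check: {allele_a!r}/{allele_b!r}"
        )
    pair = {allele_a, allele_b}
    return pair == {"A", "T"} or pair == {"C", "G"}


def harmonize_variant(
    summary: GwasSummaryRecord | tuple[str, str],
    observed_alleles: tuple[str, str],
) -> Orientation:
    """Resolve how to count risk-allele dosage from an observed allele pair.

    ``observed_alleles`` is ``(counted, other)``.  Strand flips are attempted
    only for non-ambiguous SNPs; an ambiguous summary record is rejected
    because its flip is indistinguishable from a swap.
    """
    if isinstance(summary, GwasSummaryRecord):
        risk, other = summary.risk_allele, summary.other_allele
    else:
        risk, other = summary
    counted, obs_other = observed_alleles
    if {risk, other} == {counted, obs_other}:
        return Orientation.MATCH if risk == counted else Orientation.SWAP
    snp = risk in NUCLEOTIDES and other in NUCLEOTIDES
    obs_snp = counted in NUCLEOTIDES and obs_other in NUCLEOTIDES
    if snp and obs_snp and not is_ambiguous(risk, other):
        flip_risk, flip_other = _COMPLEMENT[risk], _COMPLEMENT[other]
        if {flip_risk, flip_other} == {counted, obs_other}:
            return (
                Orientation.STRAND_FLIP
                if flip_risk == counted
                else Orientation.STRAND_FLIP_SWAP
            )
    return Orientation.FAIL


@dataclass
class RiskPanel:
    """Harmonized risk-variant panel with ln(OR) weights.

    ``variants`` has columns ``variant_id, chrom, pos, risk_allele,
    other_allele, odds_ratio, weight, hla`` (chrom/pos/hla may be absent for
    minimal inputs).  ``provenance`` counts variants removed by each
    exclusion rule.
    """

    variants: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("variant_id", "risk_allele", "other_allele", "odds_ratio", "weight"):
            if col not in self.variants.columns:
                raise FormatError(f"risk panel missing column '{col}'")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            raise ValidationError("duplicate variant IDs in panel")
        if (self.variants["weight"] < 0).any():
            raise ValidationError("negative weight in panel (orientation broken)")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.variants["weight"].to_numpy(dtype=float)

    def to_records(self) -> list[GwasSummaryRecord]:
        out = []
        for r in self.variants.itertuples(index=False):
            out.append(
                GwasSummaryRecord(
                    variant_id=r.variant_id,
                    chrom=str(getattr(r, "chrom", "0")),
                    pos=int(getattr(r, "pos", 0)),
                    risk_allele=r.risk_allele,
                    other_allele=r.other_allele,
                    odds_ratio=float(r.odds_ratio),
                )
            )
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RiskPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str}))


def build_panel(
    summary: Sequence[GwasSummaryRecord],
    dataset_a_alleles: Mapping[str, tuple[str, str]],
    dataset_b_alleles: Mapping[str, tuple[str, str]],
) -> RiskPanel:
    """Intersect summary records with two datasets and harmonize.

    ``dataset_*_alleles`` map variant id -> observed ``(counted, other)``
    allele pair for each genotyped dataset.  The returned panel contains only
    variants present in both datasets, strand-resolvable, and orientable in
    both; ``provenance`` reports ``n_summary``, ``n_intersection`` and the
    per-rule exclusion counts (disjoint: ambiguity is checked before
    orientation).
    """
    seen: set[str] = set()
    for rec in summary:
        if rec.variant_id in seen:
            raise ValidationError(f"duplicate summary variant {rec.variant_id}")
        seen.add(rec.variant_id)

    in_both = [
        rec
        for rec in summary
        if rec.variant_id in dataset_a_alleles and rec.variant_id in dataset_b_alleles
    ]
    if not in_both:
        raise ValidationError(
            "no summary variants found in both datasets — check that the "
            "variant ID schemes match (e.g. rsIDs vs chrom:pos)"
        )
    n_ambiguous = 0
    n_unorientable = 0
    rows = []
    for rec in in_both:
        if rec.is_snp and is_ambiguous(rec.risk_allele, rec.other_allele):
            n_ambiguous += 1
            continue
        # orient to OR >= 1 so weights are non-negative
        risk, other, odds = rec.risk_allele, rec.other_allele, rec.odds_ratio
        if odds < 1.0:
            risk, other, odds = other, risk, 1.0 / odds
        ok = all(
            harmonize_variant((risk, other), alleles[rec.variant_id]) is not Orientation.FAIL
            for alleles in (dataset_a_alleles, dataset_b_alleles)
        )
        if not ok:
            n_unorientable += 1
            continue
        rows.append(
            {
                "variant_id": rec.variant_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "risk_allele": risk,
                "other_allele": other,
                "odds_ratio": odds,
                "weight": math.log(odds),
            }
        )
    provenance = {
        "n_summary": len(summary),
        "n_intersection": len(in_both),
        "excluded_not_in_both": len(summary) - len(in_both),
        "excluded_ambiguous": n_ambiguous,
        "excluded_unorientable": n_unorientable,
    }
    return RiskPanel(pd.DataFrame(rows), provenance)


def align_dosages(panel: RiskPanel, dmat: DosageMatrix) -> DosageMatrix:
    """Re-express a dosage matrix as risk-allele dosages in panel order.

    Every panel variant must be present in ``dmat``; swapped orientations are
    complemented (d -> 2 - d), preserving NaN for missing entries.
    """
    sub = dmat.select_variants(panel.variant_ids)
    dosages = sub.dosages
    alleles: dict[str, tuple[str, str]] = {}
    for j, row in enumerate(panel.variants.itertuples(index=False)):
        orient = harmonize_variant(
            (row.risk_allele, row.other_allele), sub.alleles[row.variant_id]
        )
        if orient is Orientation.FAIL:
            raise ValidationError(
                f"variant {row.variant_id}: observed alleles "
                f"{sub.alleles[row.variant_id]} cannot be oriented to "
                f"({row.risk_allele}, {row.other_allele})"
            )
        if orient.swapped:
            dosages[:, j] = 2.0 - dosages[:, j]
        alleles[row.variant_id] = (row.risk_allele, row.other_allele)
    return DosageMatrix(sub.sample_ids, panel.variant_ids, dosages, alleles)
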