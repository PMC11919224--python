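"""Readers and writers for the formats the pipeline touches.

Supported inputs are GWAS risk-variant summary tables (CSV/TSV), genotype
matrices as VCF 4.x (GT or DS fields, read through cyvcf2) or as a plain
whitespace/tab dosage table, PED-style pedigree files with an optional
monozygotic-twin group column, and per-individual score tables.  A small
bundled fixture carries the published per-individual weighted polygenic risk
scores (wPRS) and HLA-DRB1*15:01 carrier status for three multicase multiple
sclerosis families (nine affected, ten unaffected relatives).

Coordinates are 1-based as in VCF.  Missing genotypes are carried as NaN,
never silently as zero; missingness policy is decided at scoring time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "GwasSummaryRecord",
    "PedigreeRecord",
    "DosageMatrix",
    "read_gwas_panel",
    "read_genotypes",
    "read_vcf",
    "read_dosage_table",
    "write_vcf",
    "write_dosage_table",
    "read_pedigree",
    "write_pedigree",
    "read_scores",
    "write_scores",
    "load_family_scores",
]

NUCLEOTIDES = frozenset("ACGT")

#: score-table groups used throughout the pipeline
GROUPS = ("case", "control", "familial_case", "unaffected_relative")

_MISSING_TOKENS = {"", "0", ".", "na", "nan", "none"}

_SEX_CODES = {
    "1": "male", "m": "male", "male": "male",
    "2": "female", "f": "female", "female": "female",
    "0": "unknown", "-9": "unknown", "unknown": "unknown",
}
# PED convention: 1 = unaffected, 2 = affected
_AFFECTION_CODES = {
    "2": "affected", "affected": "affected", "+": "affected",
    "1": "unaffected", "unaffected": "unaffected", "-": "unaffected",
    "0": "unknown", "-9": "unknown", "unknown": "unknown",
}


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One GWAS risk-variant association: risk allele and its odds ratio.

    ``risk_allele``/``other_allele`` are single nucleotides for SNPs, or
    arbitrary tokens (e.g. ``P``/``A`` for present/absent) for HLA-allele
    pseudo-markers, which bypass nucleotide strand logic downstream.
    """

    variant_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValidationError(
                f"variant {self.variant_id}: odds_ratio must be > 0, got {self.odds_ratio}"
            )
        if self.risk_allele == self.other_allele:
            raise ValidationError(
                f"variant {self.variant_id}: risk and other allele are identical"
            )

    @property
    def is_snp(self) -> bool:
        return self.risk_allele in NUCLEOTIDES and self.other_allele in NUCLEOTIDES


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree member; founders have both parent ids set to None."""

    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    mz_group: str | None = None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ValidationError(
                f"individual {self.individual_id}: parents must be both present or both missing"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"individual {self.individual_id}: bad sex {self.sex!r}")
        if self.affection not in ("affected", "unaffected", "unknown"):
            raise ValidationError(
                f"individual {self.individual_id}: bad affection {self.affection!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class DosageMatrix:
    """Individuals x variants matrix of allele dosages in [0, 2].

    ``dosages[i, j]`` counts copies of the *counted* allele of variant ``j``
    carried by sample ``i`` (reals allowed, for imputed data); missing entries
    are NaN.  ``alleles`` maps each variant id to ``(counted, other)``; for a
    VCF source the counted allele is ALT.  ``positions`` optionally maps
    variant ids to ``(chrom, pos)``.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    alleles: dict[str, tuple[str, str]]
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValidationError("dosage matrix dimensions do not match id lists")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.variant_ids)) != m:
            raise ValidationError("duplicate variant IDs")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0,2] for sample {self.sample_ids[i]}, "
                f"variant {self.variant_ids[j]}: {self.dosages[i, j]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def variant_index(self) -> dict[str, int]:
        return {v: j for j, v in enumerate(self.variant_ids)}

    def select_variants(self, ids: Sequence[str]) -> "DosageMatrix":
        idx = self.variant_index()
        missing = [v for v in ids if v not in idx]
        if missing:
            raise ValidationError(f"variants not in matrix: {missing[:5]}")
        cols = [idx[v] for v in ids]
        return DosageMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(ids),
            dosages=self.dosages[:, cols].copy(),
            alleles={v: self.alleles[v] for v in ids},
            positions=None if self.positions is None
            else {v: self.positions[v] for v in ids if v in self.positions},
        )

    def select_samples(self, ids: Sequence[str]) -> "DosageMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in ids]
        return DosageMatrix(
            sample_ids=list(ids),
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[rows, :].copy(),
            alleles=dict(self.alleles),
            positions=self.positions,
        )


# ---------------------------------------------------------------------------
# GWAS summary tables

_PANEL_COLUMNS = ("variant_id", "chrom", "pos", "risk_allele", "other_allele", "odds_ratio")


def read_gwas_panel(path: str | Path) -> list[GwasSummaryRecord]:
    """Read a GWAS risk-variant summary table (CSV/TSV, header required).

    Expects columns ``variant_id, chrom, pos, risk_allele, other_allele,
    odds_ratio`` (case-insensitive); rows are returned in file order.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _PANEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    records: list[GwasSummaryRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = dict(zip(df.columns, row))
        if all(pd.isna(v) or str(v).strip() == "" for v in d.values()):
            continue
        try:
            odds = float(d["odds_ratio"])
        except (TypeError, ValueError):
            raise FormatError(f"{path} line {i}: odds_ratio {d['odds_ratio']!r} not numeric")
        if not odds > 0:
            raise ValidationError(f"{path} line {i}: odds_ratio must be > 0, got {odds}")
        records.append(
            GwasSummaryRecord(
                variant_id=str(d["variant_id"]).strip(),
                chrom=str(d["chrom"]).strip(),
                pos=int(float(d["pos"])),
                risk_allele=str(d["risk_allele"]).strip(),
                other_allele=str(d["other_allele"]).strip(),
                odds_ratio=odds,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Genotypes

def read_genotypes(path: str | Path) -> DosageMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF reader, otherwise dosage table."""
    p = Path(path)
    if p.suffix == ".vcf" or p.name.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_dosage_table(p)


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read biallelic variants from a VCF; DS preferred over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample IDs in VCF header")
    variant_ids: list[str] = []
    alleles: dict[str, tuple[str, str]] = {}
    positions: dict[str, tuple[str, int]] = {}
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValidationError(
                f"{path}: variant {v.ID or f'{v.CHROM}:{v.POS}'} is not biallelic"
            )
        vid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}"
        try:
            ds = v.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < -0.5, np.nan, col)  # sentinel for missing DS
        else:
            gt = np.asarray(v.genotypes, dtype=object)
            col = np.empty(len(samples), dtype=float)
            for i, g in enumerate(gt):
                a, b = g[0], g[1]
                col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        variant_ids.append(vid)
        alleles[vid] = (v.ALT[0], v.REF)
        positions[vid] = (str(v.CHROM), int(v.POS))
        cols.append(col)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return DosageMatrix(samples, variant_ids, dosages, alleles, positions)


def write_vcf(dmat: DosageMatrix, path: str | Path) -> None:
    """Write a DosageMatrix as an uncompressed VCF.

    Integral dosage matrices are written as GT genotypes (counted allele =
    ALT), anything fractional as a DS field.  Missing entries become ``./.``
    or ``DS=.``.
    """
    finite = dmat.dosages[np.isfinite(dmat.dosages)]
    as_gt = np.allclose(finite, np.round(finite)) if finite.size else True
    positions = dmat.positions or {
        v: ("1", j + 1) for j, v in enumerate(dmat.variant_ids)
    }
    chroms = []
    for v in dmat.variant_ids:
        c = positions[v][0]
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        if as_gt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dmat.sample_ids) + "\n")
        order = sorted(
            range(len(dmat.variant_ids)),
            key=lambda j: (chroms.index(positions[dmat.variant_ids[j]][0]),
                           positions[dmat.variant_ids[j]][1]),
        )
        for j in order:
            vid = dmat.variant_ids[j]
            counted, other = dmat.alleles[vid]
            chrom, pos = positions[vid]
            col = dmat.dosages[:, j]
            if as_gt:
                fields = []
                for d in col:
                    if not np.isfinite(d):
                        fields.append("./.")
                    else:
                        k = int(round(d))
                        fields.append(["0/0", "0/1", "1/1"][k])
                fmt = "GT"
            else:
                fields = ["." if not np.isfinite(d) else f"{d:.6g}" for d in col]
                fmt = "DS"
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{other}\t{counted}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(fields) + "\n"
            )


def read_dosage_table(path: str | Path) -> DosageMatrix:
    """Read a plain dosage table: variant_id, allele1 (counted), allele2, then
    one column per sample; missing entries as NA."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    lower = [c.lower() for c in df.columns]
    for col in ("variant_id", "allele1", "allele2"):
        if col not in lower:
            raise FormatError(f"{path}: missing required column '{col}'")
    samples = [c for c in df.columns if c.lower() not in ("variant_id", "allele1", "allele2")]
    variant_ids = [str(v).strip() for v in df[df.columns[lower.index("variant_id")]]]
    a1 = df[df.columns[lower.index("allele1")]]
    a2 = df[df.columns[lower.index("allele2")]]
    alleles = {
        v: (str(x).strip(), str(y).strip()) for v, x, y in zip(variant_ids, a1, a2)
    }
    vals = df[samples].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    return DosageMatrix(samples, variant_ids, vals, alleles)


def write_dosage_table(dmat: DosageMatrix, path: str | Path) -> None:
    rows = {"variant_id": dmat.variant_ids,
            "allele1": [dmat.alleles[v][0] for v in dmat.variant_ids],
            "allele2": [dmat.alleles[v][1] for v in dmat.variant_ids]}
    df = pd.DataFrame(rows)
    for i, s in enumerate(dmat.sample_ids):
        df[s] = dmat.dosages[i, :]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigrees

def read_pedigree(path: str | Path) -> list[PedigreeRecord]:
    """Read a whitespace-delimited PED-style pedigree.

    Columns: family_id, individual_id, father_id, mother_id, sex, affection,
    and an optional 7th MZ-twin group column.  ``0``/``NA``/``.`` mark missing
    parents and missing MZ group.  Referenced parents must appear as rows;
    cycles and malformed MZ groups are rejected.
    """
    records: list[PedigreeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path} line {lineno}: expected >= 6 columns")
            fam, iid, fid, mid, sex, aff = parts[:6]
            mz = parts[6] if len(parts) > 6 else ""
            sex_l, aff_l = sex.lower(), aff.lower()
            if sex_l not in _SEX_CODES:
                raise FormatError(f"{path} line {lineno}: bad sex code {sex!r}")
            if aff_l not in _AFFECTION_CODES:
                raise FormatError(f"{path} line {lineno}: bad affection code {aff!r}")
            records.append(
                PedigreeRecord(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid.lower() in _MISSING_TOKENS else fid,
                    mother_id=None if mid.lower() in _MISSING_TOKENS else mid,
                    sex=_SEX_CODES[sex_l],
                    affection=_AFFECTION_CODES[aff_l],
                    mz_group=None if mz.lower() in _MISSING_TOKENS else mz,
                )
            )
    validate_pedigree(records)
    return records


def validate_pedigree(records: Sequence[PedigreeRecord]) -> None:
    """Check parent references, acyclicity and MZ-group invariants."""
    by_id: dict[str, PedigreeRecord] = {}
    for r in records:
        if r.individual_id in by_id:
            raise ValidationError(f"duplicate individual ID {r.individual_id}")
        by_id[r.individual_id] = r
    for r in records:
        for pid in (r.father_id, r.mother_id):
            if pid is not None and pid not in by_id:
                raise ValidationError(
                    f"individual {r.individual_id}: unknown parent ID {pid}"
                )
        if r.father_id is not None and by_id[r.father_id].sex == "female":
            raise ValidationError(f"father {r.father_id} recorded as female")
        if r.mother_id is not None and by_id[r.mother_id].sex == "male":
            raise ValidationError(f"mother {r.mother_id} recorded as male")

    # cycle check: walk child -> parent edges depth-first
    state: dict[str, int] = {}  # 0 in progress, 1 done

    def visit(iid: str, stack: list[str]) -> None:
        if state.get(iid) == 1:
            return
        if state.get(iid) == 0:
            raise ValidationError(f"pedigree cycle involving individual {iid}")
        state[iid] = 0
        r = by_id[iid]
        for pid in (r.father_id, r.mother_id):
            if pid is not None:
                visit(pid, stack + [iid])
        state[iid] = 1

    for iid in by_id:
        visit(iid, [])

    groups: dict[str, list[PedigreeRecord]] = {}
    for r in records:
        if r.mz_group is not None:
            groups.setdefault(f"{r.family_id}:{r.mz_group}", []).append(r)
    for key, members in groups.items():
        if len(members) == 1:
            warnings.warn(f"MZ group {key} has a single member", stacklevel=2)
            continue
        parents = {(m.father_id, m.mother_id) for m in members}
        sexes = {m.sex for m in members}
        if len(parents) != 1 or members[0].is_founder:
            raise ValidationError(f"MZ group {key}: co-twins must share both parents")
        if len(sexes) != 1:
            raise ValidationError(f"MZ group {key}: co-twins must share sex")


def write_pedigree(records: Sequence[PedigreeRecord], path: str | Path) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    aff_out = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        r.individual_id,
                        r.father_id or "0",
                        r.mother_id or "0",
                        sex_out[r.sex],
                        aff_out[r.affection],
                        r.mz_group or "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Score tables

_SCORE_COLUMNS = ("family_id", "individual_id", "group", "wprs")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    for col in _SCORE_COLUMNS:
        if col not in scores.columns:
            raise FormatError(f"score table missing column '{col}'")
    scores.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"family_id": str, "individual_id": str, "group": str})
    for col in _SCORE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: score table missing column '{col}'")
    df["wprs"] = pd.to_numeric(df["wprs"])
    return df


def load_family_scores() -> pd.DataFrame:
    """Reference per-individual wPRS for three multicase MS families.

    Returns a score table of 19 rows — 9 familial cases and 10 unaffected
    relatives across families 1-3 — with each individual's wPRS and
    HLA-DRB1*15:01 carrier status (``+/+``, ``+/-`` or ``-/-``).
    """
    with resources.files("famprs.data").joinpath("family_scores.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"family_id": str, "individual_id": str})
    df["group"] = np.where(df["affected"] == 1, "familial_case", "unaffected_relative")
    df["wprs"] = pd.to_numeric(df["wprs"])
    return df[["family_id", "individual_id", "group", "wprs", "hla_drb1_1501"]]
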