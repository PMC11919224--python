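"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library code paths they check:
Welch statistics from the textbook formula, AUC by exhaustive pair
counting, and kinship by single-locus gene-dropping Monte Carlo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famprs.data_io import PedigreeRecord
from famprs.gwas_panel import RiskPanel


# ---------------------------------------------------------------------------
# Oracles

def welch_oracle(a, b):
    """Direct Welch-Satterthwaite computation: (t, df, p_two_sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def auc_oracle(cases, controls):
    """AUC by exhaustive case-control pair counting, ties worth one half."""
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(cases) * len(controls))


def gene_drop_kinship(records, pairs, n_drops, rng):
    """Monte-Carlo kinship by dropping labelled founder alleles down the
    pedigree; returns {(a, b): (estimate, standard_error)}.

    MZ co-twins share the drop of their first-listed member.  The kinship of
    a pair is the average over the four allele pairings of the probability
    of identity by descent.
    """
    by_id = {r.individual_id: r for r in records}
    rep, groups = {}, {}
    for r in records:
        if r.mz_group is not None:
            key = (r.family_id, r.mz_group)
            groups.setdefault(key, r.individual_id)
            rep[r.individual_id] = groups[key]
        else:
            rep[r.individual_id] = r.individual_id
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    counter = [0]

    def get(iid):
        g = rep[iid]
        if g in alleles:
            return alleles[g]
        r = by_id[g]
        if r.father_id is None:
            a = np.full(n_drops, counter[0], dtype=np.int32)
            b = np.full(n_drops, counter[0] + 1, dtype=np.int32)
            counter[0] += 2
        else:
            fa, ma = get(r.father_id), get(r.mother_id)
            a = np.where(rng.random(n_drops) < 0.5, fa[0], fa[1])
            b = np.where(rng.random(n_drops) < 0.5, ma[0], ma[1])
        alleles[g] = (a, b)
        return alleles[g]

    out = {}
    for x, y in pairs:
        ax, ay = get(x), get(y)
        v = (
            (ax[0] == ay[0]).astype(float)
            + (ax[0] == ay[1])
            + (ax[1] == ay[0])
            + (ax[1] == ay[1])
        ) / 4.0
        out[(x, y)] = (float(v.mean()), float(v.std(ddof=1) / np.sqrt(n_drops)))
    return out


def random_pedigree(rng, fid="R"):
    """Random 3-generation pedigree with sibs, cousins, half-sibs and an
    optional MZ pair; acyclic by construction."""
    recs: list[PedigreeRecord] = []
    counter = [0]

    def new(sex, father=None, mother=None, mz=None):
        counter[0] += 1
        iid = f"{fid}{counter[0]}"
        recs.append(
            PedigreeRecord(fid, iid, father_id=father, mother_id=mother,
                           sex=sex, mz_group=mz)
        )
        return iid

    f1, m1 = new("male"), new("female")
    f2, m2 = new("male"), new("female")
    mz = bool(rng.random() < 0.5)
    kids1 = [new("male" if (i == 0 or (mz and i == 1)) else
                 ("male" if rng.random() < 0.5 else "female"),
                 f1, m1, mz="tw" if (mz and i < 2) else None)
             for i in range(int(rng.integers(2, 5)))]
    kids2 = [new("female" if i == 0 else ("male" if rng.random() < 0.5 else "female"),
                 f2, m2)
             for i in range(int(rng.integers(2, 4)))]
    # grandchildren: kids1[0] x kids2[0], plus a half-sib via a second mate
    for _ in range(int(rng.integers(1, 4))):
        new("male" if rng.random() < 0.5 else "female", kids1[0], kids2[0])
    mate = new("female")
    new("male" if rng.random() < 0.5 else "female", kids1[0], mate)
    return recs


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20240516)


@pytest.fixture
def small_panel():
    """Three oriented variants with ORs 2.9, 1.2, 1.0."""
    rows = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chrom": ["6", "1", "2"],
            "pos": [32_600_000, 1_000_000, 2_000_000],
            "risk_allele": ["T", "A", "C"],
            "other_allele": ["C", "G", "T"],
            "odds_ratio": [2.9, 1.2, 1.0],
        }
    )
    rows["weight"] = np.log(rows["odds_ratio"])
    return RiskPanel(rows)


def family1_structure():
    """Two parents and seven genotyped offspring-generation siblings."""
    parents = [
        PedigreeRecord("1", "1-1", sex="male"),
        PedigreeRecord("1", "1-2", sex="female"),
    ]
    kids = [
        PedigreeRecord("1", f"1-{i}", father_id="1-1", mother_id="1-2",
                       sex="female" if i % 2 else "male",
                       affection="affected" if i in (3, 4, 5) else "unaffected")
        for i in (3, 4, 5, 7, 8, 9, 10)
    ]
    return parents + kids


@pytest.fixture
def family1_pedigree():
    return family1_structure()
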