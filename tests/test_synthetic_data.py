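import numpy as np
import pandas as pd
import pytest

from famprs.cohort_stats import roc_auc
from famprs.errors import ValidationError
from famprs.gwas_panel import build_panel
from famprs.synthetic_data import (
    SimulationConfig,
    ascertain_case_control,
    ascertain_multicase_families,
    make_family_template,
    simulate_family,
    simulate_panel,
    simulate_population,
)


@pytest.fixture(scope="module")
def default_panel():
    cfg = SimulationConfig()
    panel, freqs = simulate_panel(cfg, np.random.default_rng(101))
    return cfg, panel, freqs


# ---------------------------------------------------------------------------
# Panel

def test_default_panel_shape(default_panel):
    cfg, panel, freqs = default_panel
    assert len(panel) == 167
    assert int(panel.variants["hla"].sum()) == 26
    assert (panel.variants["odds_ratio"] == 2.9).sum() == 1
    assert panel.variants.loc[panel.variants["odds_ratio"].idxmax(), "hla"]
    others = panel.variants["odds_ratio"][panel.variants["odds_ratio"] != 2.9]
    assert others.between(1.05, 1.6).all()
    assert ((freqs > 0) & (freqs < 1)).all()


def test_panel_survives_harmonization_unchanged(default_panel):
    _, panel, _ = default_panel
    obs = {
        r.variant_id: (r.risk_allele, r.other_allele)
        for r in panel.variants.itertuples(index=False)
    }
    rebuilt = build_panel(panel.to_records(), obs, obs)
    assert len(rebuilt) == len(panel)
    np.testing.assert_allclose(rebuilt.weights, panel.weights, atol=1e-12)


def test_panel_seed_reproducible():
    cfg = SimulationConfig()
    p1, f1 = simulate_panel(cfg, np.random.default_rng(5))
    p2, f2 = simulate_panel(cfg, np.random.default_rng(5))
    pd.testing.assert_frame_equal(p1.variants, p2.variants)
    np.testing.assert_array_equal(f1, f2)


def test_single_variant_panel():
    cfg = SimulationConfig(n_variants=1, n_hla=1)
    panel, _ = simulate_panel(cfg, np.random.default_rng(0))
    assert len(panel) == 1
    assert panel.variants["odds_ratio"].iloc[0] == 2.9


# ---------------------------------------------------------------------------
# Population under the liability-threshold model

def test_genotype_frequencies_match_input(default_panel):
    cfg, panel, freqs = default_panel
    pop = simulate_population(panel, freqs, 3000, cfg, np.random.default_rng(7))
    obs = pop.dosages.dosages.mean(axis=0) / 2.0
    se = np.sqrt(freqs * (1 - freqs) / (2 * 3000))
    assert (np.abs(obs - freqs) < 5 * se + 1e-9).mean() > 0.98


def test_prevalence_near_target(default_panel):
    cfg, panel, freqs = default_panel
    pop = simulate_population(panel, freqs, 20000, cfg, np.random.default_rng(8))
    assert pop.affected.mean() == pytest.approx(cfg.disease_prevalence, abs=0.01)


def test_null_h2_gives_no_discrimination(default_panel):
    _, panel, freqs = default_panel
    cfg = SimulationConfig(liability_h2_polygenic=0.0)
    pop = simulate_population(panel, freqs, 4000, cfg, np.random.default_rng(9))
    assert 50 < pop.affected.sum() < 4000
    auc = roc_auc(pop.score, pop.affected.astype(int)).auc
    assert auc == pytest.approx(0.5, abs=0.08)


def test_ascertain_case_control_counts(default_panel):
    cfg, panel, freqs = default_panel
    pop = simulate_population(panel, freqs, 15000, cfg, np.random.default_rng(10))
    rng = np.random.default_rng(11)
    cohort, labels = ascertain_case_control(pop, 300, 500, rng)
    assert (labels["group"] == "case").sum() == 300
    assert (labels["group"] == "control").sum() == 500
    assert cohort.shape == (800, 167)
    with pytest.raises(ValidationError, match="requested"):
        ascertain_case_control(pop, 14000, 500, rng)


# ---------------------------------------------------------------------------
# Families

def test_mendelian_transmission_constraints(default_panel):
    cfg, panel, freqs = default_panel
    rng = np.random.default_rng(12)
    template = make_family_template("F1", rng, n_offspring=6, mz_pair=True)
    fam = simulate_family(panel, freqs, template, cfg, rng)
    d = fam.dosages
    idx = {s: i for i, s in enumerate(d.sample_ids)}
    by_id = {r.individual_id: r for r in fam.pedigree}
    for r in fam.pedigree:
        child = d.dosages[idx[r.individual_id]]
        assert np.isin(child, [0.0, 1.0, 2.0]).all()
        if not r.is_founder:
            fa = d.dosages[idx[r.father_id]]
            ma = d.dosages[idx[r.mother_id]]
            lower = (fa == 2).astype(int) + (ma == 2).astype(int)
            upper = 2 - (fa == 0).astype(int) - (ma == 0).astype(int)
            assert (child >= lower).all() and (child <= upper).all()
    # MZ pair carries identical genotypes
    tw = [r.individual_id for r in fam.pedigree if r.mz_group is not None]
    assert len(tw) == 2
    np.testing.assert_array_equal(d.dosages[idx[tw[0]]], d.dosages[idx[tw[1]]])


def test_heterozygous_parent_transmits_half(default_panel):
    cfg, _, _ = default_panel
    big_cfg = SimulationConfig(n_variants=4000, n_hla=1, freq_range=(0.5, 0.5))
    panel, freqs = simulate_panel(big_cfg, np.random.default_rng(13))
    rng = np.random.default_rng(14)
    template = make_family_template("T", rng, n_offspring=2, mz_pair=False,
                                    n_grandchildren=0)
    fam = simulate_family(panel, freqs, template, big_cfg, rng)
    d = fam.dosages
    idx = {s: i for i, s in enumerate(d.sample_ids)}
    fa, ma = d.dosages[idx["T-f"]], d.dosages[idx["T-m"]]
    child = d.dosages[idx["T-o1"]]
    informative = (fa == 1) & (ma == 0)
    transmitted = child[informative]  # dosage = allele from the het father
    n = informative.sum()
    assert n > 200
    assert abs(transmitted.mean() - 0.5) < 4 * np.sqrt(0.25 / n)


def test_template_missing_parent_rejected(default_panel):
    cfg, panel, freqs = default_panel
    from famprs.data_io import PedigreeRecord

    bad = [
        PedigreeRecord("X", "only", sex="female"),
        PedigreeRecord("X", "kid", father_id="ghost", mother_id="only", sex="male"),
    ]
    with pytest.raises(ValidationError, match="missing parent"):
        simulate_family(panel, freqs, bad, cfg, np.random.default_rng(0))


def test_multicase_ascertainment_criterion(default_panel):
    cfg, panel, freqs = default_panel
    fams, attempts = ascertain_multicase_families(
        panel, freqs, cfg, np.random.default_rng(15)
    )
    assert len(fams) == cfg.n_families
    assert all(f.n_affected >= cfg.min_affected_per_family for f in fams)
    assert attempts >= len(fams)


def test_min_affected_zero_accepts_first_families(default_panel):
    cfg0, panel, freqs = default_panel
    cfg = SimulationConfig(min_affected_per_family=0, n_families=2)
    fams, attempts = ascertain_multicase_families(
        panel, freqs, cfg, np.random.default_rng(16)
    )
    assert attempts == 2 and len(fams) == 2


def test_impossible_criterion_exhausts_attempts(default_panel):
    cfg0, panel, freqs = default_panel
    cfg = SimulationConfig(min_affected_per_family=50, max_family_attempts=20)
    with pytest.raises(ValidationError, match="exhausted"):
        ascertain_multicase_families(panel, freqs, cfg, np.random.default_rng(17))


def test_unascertained_family_mean_is_unbiased(default_panel):
    cfg, panel, freqs = default_panel
    free = SimulationConfig(min_affected_per_family=0, n_families=150)
    fams, _ = ascertain_multicase_families(
        panel, freqs, free, np.random.default_rng(18)
    )
    founders = [
        f.score[i]
        for f in fams
        for i, r in enumerate(f.pedigree)
        if r.is_founder
    ]
    theory_mean = float(np.sum(2 * freqs * panel.weights))
    theory_sd = float(np.sqrt(np.sum(panel.weights**2 * 2 * freqs * (1 - freqs))))
    se = theory_sd / np.sqrt(len(founders))
    assert abs(np.mean(founders) - theory_mean) < 4 * se


def test_ascertained_families_have_elevated_scores(default_panel):
    cfg, panel, freqs = default_panel
    pop = simulate_population(panel, freqs, 8000, cfg, np.random.default_rng(19))
    control_mean = pop.score[~pop.affected].mean()
    many = SimulationConfig(n_families=10)
    fams, _ = ascertain_multicase_families(
        panel, freqs, many, np.random.default_rng(20)
    )
    aff = np.concatenate([f.score[f.affected] for f in fams])
    unaff = np.concatenate([f.score[~f.affected] for f in fams])
    assert aff.mean() > control_mean
    assert unaff.mean() > control_mean
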