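import numpy as np
import pytest
import statsmodels.api as sm
from scipy import linalg
from scipy.stats import norm

from famprs.data_io import PedigreeRecord
from famprs.errors import ValidationError
from famprs.kinship_mm import (
    fit_polygenic_model,
    inverse_normalise,
    kinship_coefficient,
    kinship_matrix,
    phi2_matrix,
    test_group_difference as group_difference,
)

from conftest import gene_drop_kinship, random_pedigree


def _nuclear():
    return [
        PedigreeRecord("f", "dad", sex="male"),
        PedigreeRecord("f", "mum", sex="female"),
        PedigreeRecord("f", "c1", father_id="dad", mother_id="mum", sex="male"),
        PedigreeRecord("f", "c2", father_id="dad", mother_id="mum", sex="female"),
    ]


def _cousins():
    ped = _nuclear()
    ped += [
        PedigreeRecord("f", "w1", sex="female"),
        PedigreeRecord("f", "h2", sex="male"),
        PedigreeRecord("f", "k1", father_id="c1", mother_id="w1", sex="male"),
        PedigreeRecord("f", "k2", father_id="h2", mother_id="c2", sex="female"),
    ]
    return ped


def _mz_family():
    return [
        PedigreeRecord("f", "dad", sex="male"),
        PedigreeRecord("f", "mum", sex="female"),
        PedigreeRecord("f", "t1", father_id="dad", mother_id="mum", sex="male", mz_group="tw"),
        PedigreeRecord("f", "t2", father_id="dad", mother_id="mum", sex="male", mz_group="tw"),
        PedigreeRecord("f", "w1", sex="female"),
        PedigreeRecord("f", "w2", sex="female"),
        PedigreeRecord("f", "k1", father_id="t1", mother_id="w1", sex="male"),
        PedigreeRecord("f", "k2", father_id="t2", mother_id="w2", sex="female"),
    ]


# ---------------------------------------------------------------------------
# Kinship coefficients

@pytest.mark.parametrize(
    "pair,expected",
    [(("dad", "c1"), 0.25), (("c1", "c2"), 0.25), (("dad", "mum"), 0.0),
     (("dad", "dad"), 0.5)],
)
def test_textbook_kinship_nuclear(pair, expected):
    assert kinship_coefficient(_nuclear(), *pair) == expected


def test_first_cousins_and_avuncular():
    ped = _cousins()
    assert kinship_coefficient(ped, "k1", "k2") == 0.0625
    assert kinship_coefficient(ped, "c1", "k2") == 0.125  # uncle-niece


def test_mz_twins_are_genetically_identical():
    ped = _mz_family()
    assert kinship_coefficient(ped, "t1", "t2") == 0.5
    _, phi2 = phi2_matrix(ped, ["t1", "t2"])
    assert phi2[0, 1] == 1.0
    # children of MZ co-twins by different spouses are genetic half-sibs
    assert kinship_coefficient(ped, "k1", "k2") == 0.125
    # and an MZ twin is a genetic parent of the co-twin's child
    assert kinship_coefficient(ped, "t1", "k2") == 0.25


def test_inbred_child_of_sibs_has_elevated_self_kinship():
    ped = _nuclear() + [
        PedigreeRecord("f", "inb", father_id="c1", mother_id="c2", sex="male")
    ]
    assert kinship_coefficient(ped, "inb", "inb") == 0.5 * (1 + 0.25)


def test_unknown_individual_rejected():
    with pytest.raises(ValidationError, match="unknown"):
        kinship_coefficient(_nuclear(), "dad", "nobody")


def test_gene_drop_oracle_agrees_on_mz_pedigree(rng):
    ped = _mz_family()
    pairs = [("t1", "t2"), ("k1", "k2"), ("t1", "k2"), ("dad", "k1")]
    mc = gene_drop_kinship(ped, pairs, n_drops=100_000, rng=rng)
    for pair, (est, se) in mc.items():
        exact = kinship_coefficient(ped, *pair)
        assert abs(est - exact) < 4 * max(se, 1e-4)


def test_phi2_psd_on_random_pedigrees():
    for seed in range(5):
        ped = random_pedigree(np.random.default_rng(seed))
        _, phi2 = phi2_matrix(ped)
        assert np.allclose(phi2, phi2.T)
        assert linalg.eigvalsh(phi2).min() >= -1e-8
        assert np.diag(phi2).min() >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# Inverse-normal transform

def test_blom_quantiles_n5():
    x = [10.0, 30.0, 20.0, 50.0, 40.0]
    out = inverse_normalise(x)
    expected = norm.ppf((np.array([1, 3, 2, 5, 4]) - 0.375) / 5.25)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_inverse_normal_monotone_and_symmetric(rng):
    x = rng.normal(size=101)
    out = inverse_normalise(x)
    assert (np.argsort(out) == np.argsort(x)).all()
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.sort(out), -np.sort(-out)[::-1], atol=1e-12)


def test_inverse_normal_invariant_under_monotone_transform(rng):
    x = rng.lognormal(size=50)
    np.testing.assert_allclose(
        inverse_normalise(x), inverse_normalise(np.log(x)), atol=1e-12
    )


def test_inverse_normal_ties_share_value():
    out = inverse_normalise([1.0, 2.0, 2.0, 3.0])
    assert out[1] == out[2]


def test_inverse_normal_rejects_constant():
    with pytest.raises(ValidationError):
        inverse_normalise([1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Polygenic mixed model

def test_identity_phi2_reproduces_ols(rng):
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n)
    fit = fit_polygenic_model(y, X, np.eye(n), test_col=1)
    ols = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.beta, ols.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ols.bse, atol=1e-6)
    assert fit.wald_p == pytest.approx(ols.pvalues[1], abs=1e-6)


def test_no_genetic_variance_recovers_h2_zero(rng):
    block = np.full((4, 4), 0.5)
    np.fill_diagonal(block, 1.0)
    K = linalg.block_diag(*[block] * 25)
    h2s = []
    for _ in range(50):
        y = 2.0 + rng.normal(size=100)  # pure environmental noise
        h2s.append(fit_polygenic_model(y, np.ones((100, 1)), K).h2)
    assert np.mean(h2s) < 0.1


def test_sibship_h2_recovery_quick(rng):
    block = np.full((6, 6), 0.5)
    np.fill_diagonal(block, 1.0)
    K = linalg.block_diag(*[block] * 50)
    L = np.linalg.cholesky(block)
    h2s = []
    for _ in range(30):
        g = np.concatenate([L @ rng.normal(size=6) for _ in range(50)]) * np.sqrt(0.6)
        y = 1.0 + g + rng.normal(size=300) * np.sqrt(0.4)
        h2s.append(fit_polygenic_model(y, np.ones((300, 1)), K).h2)
    assert np.mean(h2s) == pytest.approx(0.6, abs=0.15)


def test_ml_likelihood_dominates_ols_embedding(rng):
    block = np.full((5, 5), 0.5)
    np.fill_diagonal(block, 1.0)
    K = linalg.block_diag(*[block] * 10)
    L = np.linalg.cholesky(block)
    g = np.concatenate([L @ rng.normal(size=5) for _ in range(10)])
    y = g + 0.5 * rng.normal(size=50)
    n = 50
    fit = fit_polygenic_model(y, np.ones((n, 1)), K)
    rss = np.sum((y - y.mean()) ** 2)
    ll_ols = -0.5 * (n * np.log(2 * np.pi * rss / n) + n)
    assert fit.loglik >= ll_ols - 1e-8


def test_non_psd_phi2_rejected(rng):
    K = -np.eye(10)
    with pytest.raises(ValidationError, match="positive semidefinite"):
        fit_polygenic_model(rng.normal(size=10), np.ones((10, 1)), K)


def test_singular_design_rejected(rng):
    n = 20
    X = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(ValidationError, match="singular"):
        fit_polygenic_model(rng.normal(size=n), X, np.eye(n), test_col=1)


def test_group_difference_antisymmetric(rng):
    a = rng.normal(1.0, 1.0, 12)
    b = rng.normal(0.0, 1.0, 40)
    f1 = group_difference(a, b)
    f2 = group_difference(b, a)
    assert f1.coef("group_a") == pytest.approx(-f2.coef("group_a"), abs=1e-6)
    assert f1.lrt_p == pytest.approx(f2.lrt_p, abs=1e-6)


def test_group_difference_with_pedigree_detects_shift(rng):
    ped = _mz_family()
    ids = [r.individual_id for r in ped]
    a = rng.normal(2.0, 1.0, len(ids))
    b = rng.normal(0.0, 1.0, 200)
    fit = group_difference(a, b, pedigree_a=ped, ids_a=ids)
    assert fit.coef("group_a") > 0
    assert fit.lrt_p < 0.05
    assert 0.0 <= fit.h2 <= 1.0
    assert fit.sigma2_g >= 0 and fit.sigma2_e >= 0
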