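"""Pedigree kinship and the polygenic linear mixed model.

Two individuals i and j have kinship coefficient phi(i, j): the probability
that one allele drawn at random from each is identical by descent.  On an
acyclic pedigree with unrelated founders it satisfies the classical
recursion

    phi(i, i) = (1 + phi(f_i, m_i)) / 2
    phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2      (i not an ancestor of j)

which gives 1/4 for parent-offspring and full siblings, 1/16 for first
cousins, and 1/2 on the diagonal of a non-inbred pedigree.  Monozygotic (MZ)
co-twins are genetically identical: each MZ group is collapsed onto a single
genetic representative before the recursion, so co-twins receive
phi = phi(i, i) and their descendants relate through the shared genome
(children of two co-twins are genetic half-siblings).  The relationship
matrix used by the mixed model is Phi2 = 2 * phi — diagonal 1 for non-inbred
individuals, off-diagonal 1 for MZ co-twins.

The quantitative-trait model is

    y = X beta + g + e,   g ~ N(0, sigma2_g * Phi2),   e ~ N(0, sigma2_e * I)

fitted by maximum likelihood.  Writing V = sigma2 * (h2 * Phi2 + (1-h2) * I)
with total variance sigma2 and heritability ratio h2 = sigma2_g / sigma2,
an eigendecomposition Phi2 = U diag(d) U' rotates the model into independent
coordinates with variances sigma2 * (h2 * d_k + 1 - h2); the likelihood is
then profiled over h2 in [0, 1) with GLS for beta and a closed-form sigma2
at each h2.  The group fixed effect is tested by a likelihood-ratio test
against the model without it (chi-square, 1 df) and, for reference, by a
Wald t-test whose standard error uses the degrees-of-freedom-adjusted
residual variance (so with Phi2 = I the Wald test reproduces the ordinary
least-squares t-test exactly).

Scores are rank-transformed to normality (:func:`inverse_normalise`, Blom
offset) before group comparisons, so fixed effects are in standard-deviation
units of the transformed trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import ndtri

from .data_io import PedigreeRecord, validate_pedigree
from .errors import ValidationError

__all__ = [
    "RelationshipMatrix",
    "MixedModelFit",
    "kinship_coefficient",
    "kinship_matrix",
    "phi2_matrix",
    "inverse_normalise",
    "fit_polygenic_model",
    "test_group_difference",
]

_H2_MAX = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# Kinship

class _PedigreeGraph:
    """Pedigree collapsed onto MZ genetic representatives, with memoised phi."""

    def __init__(self, records: Sequence[PedigreeRecord]):
        validate_pedigree(records)
        self.records = {r.individual_id: r for r in records}
        # representative: first-listed member of each MZ group
        rep: dict[str, str] = {}
        groups: dict[tuple[str, str], str] = {}
        for r in records:
            if r.mz_group is not None:
                key = (r.family_id, r.mz_group)
                groups.setdefault(key, r.individual_id)
                rep[r.individual_id] = groups[key]
            else:
                rep[r.individual_id] = r.individual_id
        self.rep = rep
        # parents of each representative, mapped through representatives
        self.parents: dict[str, tuple[str, str] | None] = {}
        self.depth: dict[str, int] = {}
        for r in records:
            g = rep[r.individual_id]
            if g in self.parents:
                continue
            if r.is_founder:
                self.parents[g] = None
            else:
                self.parents[g] = (rep[r.father_id], rep[r.mother_id])
        for g in self.parents:
            self._depth(g)
        self._phi: dict[tuple[str, str], float] = {}

    def _depth(self, g: str) -> int:
        if g in self.depth:
            return self.depth[g]
        p = self.parents[g]
        d = 0 if p is None else 1 + max(self._depth(p[0]), self._depth(p[1]))
        self.depth[g] = d
        return d

    def phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in self._phi:
            return self._phi[key]
        if a == b:
            p = self.parents[a]
            val = 0.5 if p is None else 0.5 * (1.0 + self.phi(p[0], p[1]))
        else:
            # recurse on the deeper individual: it cannot be an ancestor of
            # the shallower one
            i, j = (a, b) if self.depth[a] >= self.depth[b] else (b, a)
            p = self.parents[i]
            val = 0.0 if p is None else 0.5 * (self.phi(p[0], j) + self.phi(p[1], j))
        self._phi[key] = val
        return val


def kinship_coefficient(
    pedigree: Sequence[PedigreeRecord], id_a: str, id_b: str
) -> float:
    """Kinship phi(a, b); MZ co-twins return their self-kinship."""
    graph = _PedigreeGraph(pedigree)
    for i in (id_a, id_b):
        if i not in graph.records:
            raise ValidationError(f"unknown individual {i}")
    return graph.phi(graph.rep[id_a], graph.rep[id_b])


def kinship_matrix(
    pedigree: Sequence[PedigreeRecord], ids: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Kinship matrix over ``ids`` (default: all pedigree members, file order)."""
    graph = _PedigreeGraph(pedigree)
    if ids is None:
        ids = [r.individual_id for r in pedigree]
    for i in ids:
        if i not in graph.records:
            raise ValidationError(f"unknown individual {i}")
    n = len(ids)
    phi = np.empty((n, n))
    reps = [graph.rep[i] for i in ids]
    for i in range(n):
        for j in range(i, n):
            phi[i, j] = phi[j, i] = graph.phi(reps[i], reps[j])
    return list(ids), phi


@dataclass
class RelationshipMatrix:
    """Phi2 = 2 * kinship over an ordered list of individuals."""

    ids: list[str]
    phi2: np.ndarray

    @classmethod
    def from_pedigree(
        cls, pedigree: Sequence[PedigreeRecord], ids: Sequence[str] | None = None
    ) -> "RelationshipMatrix":
        ids_out, phi = kinship_matrix(pedigree, ids)
        return cls(ids_out, 2.0 * phi)


def phi2_matrix(
    pedigree: Sequence[PedigreeRecord], ids: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    ids_out, phi = kinship_matrix(pedigree, ids)
    return ids_out, 2.0 * phi


# ---------------------------------------------------------------------------
# Inverse-normal transform

def inverse_normalise(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Value at (average, tie-sharing) rank r among n maps to the standard
    normal quantile of (r - c) / (n - 2c + 1), c = 3/8.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("inverse_normalise requires n >= 2")
    if np.ptp(x) == 0:
        raise ValidationError("inverse_normalise undefined for a constant vector")
    r = stats.rankdata(x, method="average")
    return ndtri((r - offset) / (x.size - 2.0 * offset + 1.0))


# ---------------------------------------------------------------------------
# Polygenic mixed model

@dataclass
class MixedModelFit:
    """ML fit of y = X beta + g + e with cov(g) = sigma2_g * Phi2."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    n: int
    loglik_null: float | None = None
    lrt_stat: float | None = None
    lrt_p: float | None = None
    wald_t: float | None = None
    wald_p: float | None = None
    tested: str | None = None

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in zip(self.names, self.beta)},
            "se": {k: float(v) for k, v in zip(self.names, self.se)},
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "h2": self.h2,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "lrt_stat": self.lrt_stat,
            "lrt_p": self.lrt_p,
            "wald_t": self.wald_t,
            "wald_p": self.wald_p,
            "tested": self.tested,
            "n": self.n,
        }


def _profile_fit(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Maximise the likelihood over h2 for rotated data; return fit pieces."""
    n, p = Xt.shape

    def pieces(h2: float):
        w = h2 * d + (1.0 - h2)
        Xw = Xt / w[:, None]
        xtx = Xt.T @ Xw
        try:
            beta = linalg.solve(xtx, Xw.T @ yt, assume_a="pos")
        except linalg.LinAlgError:
            raise ValidationError("singular design matrix")
        resid = yt - Xt @ beta
        rss = float(resid @ (resid / w))
        if rss <= 0:
            rss = np.finfo(float).tiny
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + np.log(w).sum() + n)
        return ll, beta, sigma2, xtx, rss

    def nll(h2: float) -> float:
        return -pieces(h2)[0]

    grid = np.linspace(0.0, _H2_MAX, 26)
    vals = np.array([nll(h) for h in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        h2_hat = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        h2_hat = float(grid[k])
    ll, beta, sigma2, xtx, rss = pieces(h2_hat)
    # df-adjusted residual variance for Wald standard errors
    sigma2_u = rss / max(n - p, 1)
    cov = sigma2_u * linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return ll, beta, se, sigma2, h2_hat


def fit_polygenic_model(
    y,
    covariates,
    phi2: RelationshipMatrix | np.ndarray,
    test_col: int | None = None,
    names: Sequence[str] | None = None,
) -> MixedModelFit:
    """Fit the polygenic model; optionally LRT-test one design column.

    ``covariates`` is the full design matrix including the intercept.  When
    ``test_col`` is given, the null model without that column is also fitted
    and the likelihood-ratio p-value (chi-square, 1 df) plus a Wald t-test
    are reported for it.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K = phi2.phi2 if isinstance(phi2, RelationshipMatrix) else np.asarray(phi2, float)
    n = y.size
    if X.shape[0] != n or K.shape != (n, n):
        raise ValidationError("dimension mismatch between y, covariates and phi2")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValidationError("phi2 must be symmetric")
    d, U = linalg.eigh(K)
    if d.min() < -1e-8:
        raise ValidationError(f"phi2 is not positive semidefinite (min eig {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    ll, beta, se, sigma2, h2 = _profile_fit(yt, Xt, d)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    fit = MixedModelFit(
        beta=beta,
        se=se,
        names=list(names),
        sigma2_g=float(sigma2 * h2),
        sigma2_e=float(sigma2 * (1.0 - h2)),
        h2=float(h2),
        loglik=float(ll),
        n=n,
    )
    if test_col is not None:
        keep = [j for j in range(X.shape[1]) if j != test_col]
        if not keep:
            raise ValidationError("cannot test the only design column")
        ll0, *_ = _profile_fit(yt, Xt[:, keep], d)
        lrt = max(2.0 * (ll - ll0), 0.0)
        tstat = float(beta[test_col] / se[test_col])
        dof = max(n - X.shape[1], 1)
        fit.loglik_null = float(ll0)
        fit.lrt_stat = float(lrt)
        fit.lrt_p = float(stats.chi2.sf(lrt, df=1))
        fit.wald_t = tstat
        fit.wald_p = float(2.0 * stats.t.sf(abs(tstat), df=dof))
        fit.tested = fit.names[test_col]
    return fit


def test_group_difference(
    scores_group_a,
    scores_group_b,
    pedigree_a: Sequence[PedigreeRecord] | None = None,
    ids_a: Sequence[str] | None = None,
    sex: Sequence[int] | None = None,
) -> MixedModelFit:
    """Mixed-model contrast of group A (possibly related) vs group B.

    Scores are pooled, inverse-normalised, and modelled with an intercept, a
    group-A indicator (the tested effect, in SD units of the transformed
    trait) and optionally a sex covariate (0/1 per pooled individual, A
    first).  Group A's relationships come from ``pedigree_a`` restricted to
    ``ids_a`` (matrix order = score order); group B enters as an unrelated
    identity block.
    """
    a = np.asarray(scores_group_a, dtype=float)
    b = np.asarray(scores_group_b, dtype=float)
    if pedigree_a is not None:
        if ids_a is None:
            raise ValidationError("ids_a required when pedigree_a is given")
        if len(ids_a) != a.size:
            raise ValidationError("ids_a length does not match group A scores")
        _, K_a = phi2_matrix(pedigree_a, ids_a)
    else:
        K_a = np.eye(a.size)
    n = a.size + b.size
    K = np.eye(n)
    K[: a.size, : a.size] = K_a
    y = inverse_normalise(np.concatenate([a, b]))
    cols = [np.ones(n), np.concatenate([np.ones(a.size), np.zeros(b.size)])]
    names = ["intercept", "group_a"]
    if sex is not None:
        sx = np.asarray(sex, dtype=float)
        if sx.size != n:
            raise ValidationError("sex covariate length does not match pooled sample")
        if np.ptp(sx) > 0:  # drop a constant covariate rather than fail
            cols.append(sx)
            names.append("sex")
    X = np.column_stack(cols)
    return fit_polygenic_model(y, X, K, test_col=1, names=names)
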