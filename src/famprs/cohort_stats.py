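"""Population case-control comparisons: Welch t-test and ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ValidationError

__all__ = ["WelchResult", "RocResult", "welch_t", "roc_auc", "render_p"]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    ci_method: str


def welch_t(sample_a, sample_b) -> WelchResult:
    """Unequal-variance two-sample t-test (Welch-Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t requires at least 2 observations per sample")
    res = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(res.statistic):
        raise ValidationError("welch_t undefined: both samples have zero variance")
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=a.size,
        n_b=b.size,
    )


def _delong_auc_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong (1988) variance via placement values.

    The placement of a case is the fraction of controls it outranks (ties
    half); symmetrically for controls.  AUC is the mean placement and the
    variance combines the two empirical placement variances.
    """
    m, n = cases.size, controls.size
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v_cases = (all_ranks[:m] - case_ranks) / n          # placements of cases
    v_controls = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc = v_cases.mean()
    var = (
        (np.var(v_cases, ddof=1) / m if m > 1 else 0.0)
        + (np.var(v_controls, ddof=1) / n if n > 1 else 0.0)
    )
    return float(auc), float(var)


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """ROC curve and AUC of a score against binary labels (1 = case).

    AUC equals the Mann-Whitney U statistic scaled to [0, 1] with ties
    counted one half.  The 95% (1 - alpha) confidence interval uses the
    closed-form DeLong variance by default, or a stratified bootstrap
    (``ci_method="bootstrap"``, seeded).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if set(classes.tolist()) != {0, 1}:
        raise ValidationError("labels must contain both classes, coded 0/1")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    cases, controls = s[y == 1], s[y == 0]
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "delong":
        _, var = _delong_auc_variance(cases, controls)
        se = float(np.sqrt(var))
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            cb = rng.choice(cases, cases.size, replace=True)
            kb = rng.choice(controls, controls.size, replace=True)
            a, _ = _delong_auc_variance(cb, kb)
            reps[b] = a
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        se = float(reps.std(ddof=1))
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        se=se,
        fpr=fpr,
        tpr=tpr,
        ci_method=ci_method,
    )


def render_p(p: float, floor: float = 2.2e-16) -> str:
    """Human-readable p-value with the conventional display floor."""
    if p < floor:
        return f"< {floor:.1e}"
    return f"{p:.3g}"
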