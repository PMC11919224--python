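"""Subsampled familial-vs-population comparisons and family-level reporting.

A handful of familial scores against thousands of population scores is a
badly unbalanced Welch test.  ``subsample_compare`` therefore repeatedly
draws fixed-size random subsets of the population scores (by default 100
draws of 500, without replacement within a draw, independently across
draws) and tests the full familial vector against each subset, reporting
the spread of p-values across draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import welch_t
from .errors import ValidationError
from .prs_scoring import format_2dp, group_summary

__all__ = ["SubsampleComparison", "subsample_compare", "family_report", "render_family_table"]


@dataclass
class SubsampleComparison:
    """Per-iteration Welch results of family scores vs population subsamples.

    ``directions`` holds the sign of (family mean - subsample mean) per
    iteration.
    """

    n_iterations: int
    subsample_size: int
    seed: int | None
    p_values: np.ndarray
    t_values: np.ndarray
    directions: np.ndarray
    subsample_means: np.ndarray
    subsample_sds: np.ndarray
    family_mean: float
    family_sd: float

    @property
    def p_min(self) -> float:
        return float(self.p_values.min())

    @property
    def p_max(self) -> float:
        return float(self.p_values.max())

    def frac_significant(self, alpha: float = 0.05) -> float:
        return float((self.p_values < alpha).mean())

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "subsample_size": self.subsample_size,
            "seed": self.seed,
            "p_min": self.p_min,
            "p_max": self.p_max,
            "frac_significant_0.05": self.frac_significant(),
            "direction": int(np.sign(self.directions.sum())),
            "family_mean": self.family_mean,
            "family_sd": self.family_sd,
            "subsample_mean": float(self.subsample_means.mean()),
            "subsample_sd": float(self.subsample_sds.mean()),
            "p_values": self.p_values.tolist(),
        }


def subsample_compare(
    population_scores,
    family_scores,
    k: int = 500,
    iterations: int = 100,
    seed: int | None = None,
) -> SubsampleComparison:
    """Welch-test family scores against ``iterations`` population subsamples.

    Each iteration draws ``k`` population scores without replacement (a fresh
    independent draw per iteration) and tests the full family vector against
    it.  Seeding spawns one substream per iteration from the master seed, so
    raising ``iterations`` extends, rather than reshuffles, earlier draws.
    """
    pop = np.asarray(population_scores, dtype=float)
    fam = np.asarray(family_scores, dtype=float)
    if k > pop.size:
        raise ValidationError(f"subsample size k={k} exceeds population size {pop.size}")
    if fam.size < 2:
        raise ValidationError("need at least 2 family scores")
    streams = np.random.SeedSequence(seed).spawn(iterations)
    p = np.empty(iterations)
    t = np.empty(iterations)
    means = np.empty(iterations)
    sds = np.empty(iterations)
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        sub = pop[rng.choice(pop.size, size=k, replace=False)]
        res = welch_t(fam, sub)
        p[i] = res.p_two_sided
        t[i] = res.t
        means[i] = res.mean_b
        sds[i] = res.sd_b
    return SubsampleComparison(
        n_iterations=iterations,
        subsample_size=k,
        seed=seed,
        p_values=p,
        t_values=t,
        directions=np.sign(fam.mean() - means),
        subsample_means=means,
        subsample_sds=sds,
        family_mean=float(fam.mean()),
        family_sd=float(fam.std(ddof=1)),
    )


def family_report(scores: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Family-by-affection summary plus a Combined row pooling families.

    ``scores`` must carry ``family_id``, ``group`` (familial_case /
    unaffected_relative) and ``wprs``; an HLA status column, if present, is
    passed through to the per-individual listing.  Returns ``by_family``
    (family x group n/mean/sd), ``combined`` (group pooled across families)
    and ``individuals``.
    """
    for col in ("family_id", "group", "wprs"):
        if col not in scores.columns:
            raise ValidationError(f"score table missing column '{col}'")
    empty = [f for f, sub in scores.groupby("family_id") if len(sub) == 0]
    if empty:
        warnings.warn(f"families with no members omitted: {empty}", stacklevel=2)
    by_family = group_summary(scores, by=["family_id", "group"])
    combined = group_summary(scores, by=["group"])
    combined.insert(0, "family_id", "Combined")
    listing_cols = [c for c in scores.columns if c != "n_variants_used"]
    return {
        "by_family": by_family,
        "combined": combined,
        "individuals": scores[listing_cols].copy(),
    }


def render_family_table(report: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Two-decimal 'mean (sd)' rendering of a family report, one row per family."""
    rows = pd.concat([report["by_family"], report["combined"]], ignore_index=True)
    rows["cell"] = rows.apply(
        lambda r: f"{format_2dp(r['mean'])} ({format_2dp(r['sd'])})"
        if np.isfinite(r["sd"])
        else format_2dp(r["mean"]),
        axis=1,
    )
    return rows.pivot(index="family_id", columns="group", values="cell")
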