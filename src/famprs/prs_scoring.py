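"""Weighted polygenic risk score (wPRS) computation.

The score of an individual is the weighted sum of risk-allele dosages,

    wPRS = sum_i G_i * W_i,

where G_i in [0, 2] is the dosage of the risk allele at panel variant i and
W_i = ln(OR_i) its log odds-ratio weight.  Dosages may be fractional
(imputed); the sum extends linearly.

Missing genotypes are handled at scoring time by ``missing_policy``:
``"complete"`` (default) sums over observed variants only, and
``"mean-impute"`` substitutes 2 * p_i (the expected dosage under
Hardy-Weinberg at risk-allele frequency p_i) when frequencies are supplied.
``n_variants_used`` is reported per individual so users can filter on
completeness.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import DosageMatrix
from .errors import ValidationError
from .gwas_panel import RiskPanel

__all__ = ["score_individual", "score_cohort", "group_summary", "format_2dp"]


def _imputed(dosages: np.ndarray, weights: np.ndarray, policy: str,
             allele_freqs: np.ndarray | None) -> np.ndarray:
    if policy == "complete":
        return np.where(np.isfinite(dosages), dosages, 0.0)
    if policy == "mean-impute":
        if allele_freqs is None:
            raise ValidationError("mean-impute policy requires allele frequencies")
        freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), dosages.shape[-1:])
        return np.where(np.isfinite(dosages), dosages, 2.0 * freqs)
    raise ValidationError(f"unknown missing_policy {policy!r}")


def score_individual(
    dosages: Sequence[float] | np.ndarray,
    panel: RiskPanel,
    missing_policy: str = "complete",
    allele_freqs: Sequence[float] | None = None,
) -> tuple[float, int]:
    """Score one individual from a dosage vector aligned to panel order.

    Returns ``(wprs, n_variants_used)`` where the count is the number of
    non-missing dosages entering the sum.
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape != (len(panel),):
        raise ValidationError(
            f"dosage vector length {d.shape} does not match panel size {len(panel)}"
        )
    n_used = int(np.isfinite(d).sum())
    if n_used == 0:
        raise ValidationError("all panel variants missing: score undefined")
    w = panel.weights
    filled = _imputed(d, w, missing_policy,
                      None if allele_freqs is None else np.asarray(allele_freqs))
    return float(filled @ w), n_used


def score_cohort(
    genotypes: DosageMatrix,
    panel: RiskPanel,
    labels: Mapping[str, str] | pd.DataFrame,
    missing_policy: str = "complete",
    allele_freqs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Score every sample in a (risk-allele-aligned) dosage matrix.

    ``labels`` maps sample id -> group, or is a DataFrame with columns
    ``individual_id, group`` and optionally ``family_id``.  Returns a score
    table with columns ``family_id, individual_id, group, wprs,
    n_variants_used``, one row per sample in matrix order.
    """
    if genotypes.variant_ids != panel.variant_ids:
        raise ValidationError(
            "dosage matrix is not aligned to the panel; use gwas_panel.align_dosages"
        )
    if isinstance(labels, pd.DataFrame):
        for col in ("individual_id", "group"):
            if col not in labels.columns:
                raise ValidationError(f"labels frame missing column '{col}'")
        group_of = dict(zip(labels["individual_id"], labels["group"]))
        family_of = (
            dict(zip(labels["individual_id"], labels["family_id"]))
            if "family_id" in labels.columns
            else {}
        )
    else:
        group_of = dict(labels)
        family_of = {}
    missing = [s for s in genotypes.sample_ids if s not in group_of]
    if missing:
        raise ValidationError(f"samples without a group label: {missing[:5]}")

    d = genotypes.dosages
    n_used = np.isfinite(d).sum(axis=1).astype(int)
    if (n_used == 0).any():
        bad = genotypes.sample_ids[int(np.argmax(n_used == 0))]
        raise ValidationError(f"sample {bad}: all panel variants missing")
    w = panel.weights
    filled = _imputed(d, w, missing_policy,
                      None if allele_freqs is None else np.asarray(allele_freqs))
    wprs = filled @ w
    return pd.DataFrame(
        {
            "family_id": [family_of.get(s) for s in genotypes.sample_ids],
            "individual_id": list(genotypes.sample_ids),
            "group": [group_of[s] for s in genotypes.sample_ids],
            "wprs": wprs,
            "n_variants_used": n_used,
        }
    )


def group_summary(
    scores: pd.DataFrame, by: Sequence[str] = ("group",)
) -> pd.DataFrame:
    """Per-group n, mean and sample standard deviation (ddof=1) of wPRS.

    The SD of a singleton group is reported as NaN.  Values are returned at
    full precision; use :func:`format_2dp` for tabular rendering.
    """
    if len(scores) == 0:
        raise ValidationError("empty score table")
    by = list(by)
    for col in by + ["wprs"]:
        if col not in scores.columns:
            raise ValidationError(f"score table missing column '{col}'")
    out = (
        scores.groupby(by, dropna=False, sort=True, observed=True)["wprs"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def format_2dp(x: float) -> str:
    """Render a score statistic at two decimals, half-up on the decimal value.

    Plain float rounding would turn e.g. an exact decimal mean of 22.435
    (stored as 22.43499...) into "22.43"; re-quantizing through a short
    decimal repr gives the conventional half-up "22.44".
    """
    if x is None or not np.isfinite(x):
        return ""
    d = Decimal(repr(round(float(x), 8)))
    return str(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
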