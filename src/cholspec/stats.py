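"""Validation statistics for method-agreement and screening studies.

Implements, from first principles, the statistics used to validate a
point-of-care measurement device against a reference method and against
clinical group labels:

* Pearson product-moment correlation between paired measurements,
* Bland-Altman agreement (bias, SD of differences, 95% limits of
  agreement at bias +/- 1.96 * SD),
* coefficient of variation (100 * sample SD / mean, in percent),
* ROC curve and AUC in the Mann-Whitney pairwise formulation with ties
  counted one half, with a DeLong 95% confidence interval,
* classical one-way ANOVA (between/within mean-square F ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata

from .errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "PairedSample",
    "AgreementReport",
    "ROCReport",
    "AnovaResult",
    "pearson_correlation",
    "bland_altman",
    "coefficient_of_variation",
    "roc_auc_with_ci",
    "one_way_anova",
]

LOA_MULTIPLIER = 1.96  # conventional 95% limits-of-agreement multiplier


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement series on the same subjects.

    ``from_arrays`` applies the drop-missing policy: pairs with a NaN in
    either series are removed (the count is retained on the instance).
    """

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
            raise ValidationError("paired series must be 1-D and of equal length")
        if a.size < 2:
            raise InsufficientDataError("paired sample needs at least 2 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError(
                "paired sample contains non-finite values; use from_arrays to drop them"
            )
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @classmethod
    def from_arrays(cls, a, b, labels=None) -> "PairedSample":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValidationError("paired series must have equal length")
        keep = np.isfinite(a) & np.isfinite(b)
        kept_labels = None
        if labels is not None:
            kept_labels = tuple(l for l, k in zip(labels, keep) if k)
        return cls(a[keep], b[keep], kept_labels, int((~keep).sum()))

    @property
    def n(self) -> int:
        return self.values_a.size


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of between-method differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_diff < 0:
            raise ValidationError("sd_diff must be non-negative")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValidationError("limits of agreement must bracket the bias")

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


@dataclass(frozen=True)
class ROCReport:
    """ROC curve with AUC and DeLong confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValidationError("confidence interval must bracket the AUC")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "fpr": list(map(float, self.fpr)),
            "tpr": list(map(float, self.tpr)),
        }


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA F statistic with degrees of freedom and p-value."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
        }


def pearson_correlation(sample: PairedSample) -> float:
    """Product-moment correlation r = S_ab / sqrt(S_aa * S_bb)."""
    if sample.n < 3:
        raise InsufficientDataError("correlation needs at least 3 pairs")
    a = sample.values_a - sample.values_a.mean()
    b = sample.values_b - sample.values_b.mean()
    s_aa = float(a @ a)
    s_bb = float(b @ b)
    if s_aa == 0.0 or s_bb == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    return float(a @ b) / np.sqrt(s_aa * s_bb)


def bland_altman(sample: PairedSample, order: str = "a_minus_b") -> AgreementReport:
    """Bland-Altman agreement: bias, SD of differences, 95% limits.

    ``order`` selects the difference direction; the default is a - b
    (device minus reference when a holds device values).
    """
    if order == "a_minus_b":
        diff = sample.values_a - sample.values_b
    elif order == "b_minus_a":
        diff = sample.values_b - sample.values_a
    else:
        raise ValidationError(f"unknown difference order {order!r}")
    if diff.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=diff.size,
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CV needs at least 2 values")
    mean = float(v.mean())
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return 100.0 * float(v.std(ddof=1)) / mean


def _midrank_placements(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """DeLong structural components via midranks.

    V10[i] = P(score_neg < pos_i) + P(score_neg == pos_i)/2 over negatives,
    V01[j] symmetrically over positives; mean of either is the AUC.
    """
    m, n = scores_pos.size, scores_neg.size
    combined = np.concatenate([scores_pos, scores_neg])
    ranks_all = rankdata(combined)
    ranks_pos_within = rankdata(scores_pos)
    ranks_neg_within = rankdata(scores_neg)
    v10 = (ranks_all[:m] - ranks_pos_within) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg_within) / m
    return v10, v01


def roc_auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_direction: str = "greater",
    alpha: float = 0.05,
) -> ROCReport:
    """ROC curve, Mann-Whitney AUC (ties half-credit) and DeLong CI.

    ``labels`` are truthy for the positive class; by default a higher score
    indicates the positive class (set ``positive_direction='less'`` to
    flip).  The curve enumerates every distinct score as a threshold, so it
    starts at (0, 0) and ends at (1, 1) with non-decreasing coordinates.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([bool(l) for l in labels])
    if s.ndim != 1 or s.size != y.size:
        raise ValidationError("scores and labels must be 1-D and of equal length")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores contain non-finite values")
    if positive_direction == "less":
        s = -s
    elif positive_direction != "greater":
        raise ValidationError(f"unknown positive_direction {positive_direction!r}")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")

    pos, neg = s[y], s[~y]
    v10, v01 = _midrank_placements(pos, neg)
    auc = float(v10.mean())

    if n_pos > 1 and n_neg > 1:
        var = float(np.var(v10, ddof=1)) / n_pos + float(np.var(v01, ddof=1)) / n_neg
    else:
        var = 0.0
    se = np.sqrt(max(var, 0.0))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    ci_low = float(np.clip(auc - z * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z * se, 0.0, 1.0))

    # ROC curve over all distinct thresholds, descending
    order = np.argsort(-s, kind="mergesort")
    sorted_y = y[order]
    sorted_s = s[order]
    distinct = np.r_[np.where(np.diff(sorted_s) != 0)[0], sorted_s.size - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = np.cumsum(~sorted_y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]

    return ROCReport(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pos=n_pos,
        n_neg=n_neg,
        fpr=fpr,
        tpr=tpr,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from the SSB/SSW decomposition."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValidationError("group values must be finite")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    df_b = k - 1
    df_w = n_total - k
    if ssw == 0.0:
        raise ValidationError("zero within-group variance; F undefined")
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return AnovaResult(f_statistic=float(f_stat), p_value=p, df_between=df_b, df_within=df_w)
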