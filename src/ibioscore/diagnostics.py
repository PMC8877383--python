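"""Diagnostic evaluation of a score against a binary disease endpoint.

Covers the standard 2x2 machinery for a thresholded integer score:
confusion tables, sensitivity/specificity, odds ratios with Woolf's logit
95% confidence interval and a Pearson chi-square p-value (Fisher's exact
test available for small cells), ROC curves with trapezoidal AUC, and
threshold selection (Youden or rate-constrained).

Published studies often report only sensitivity, specificity and group
sizes; :func:`reconstruct_table` rebuilds the (possibly fractional) 2x2
cells from those rates so that odds ratios can be recomputed from the
printed numbers alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "ROCCurve",
    "confusion_at_threshold",
    "odds_ratio",
    "reconstruct_table",
    "roc_curve",
    "select_threshold",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rounding).

    Binary-float noise is suppressed at 12 significant digits first, so a
    value stored as 5.249999999999997 rounds like the intended 5.25 -> 5.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.12g}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of a positive/negative test call vs a binary endpoint.

    Cells may be fractional when the table was reconstructed from printed
    sensitivity/specificity (``reconstructed=True``).
    """

    tp: float
    fn: float
    fp: float
    tn: float
    reconstructed: bool = False

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    @property
    def n_pos(self) -> float:
        return self.tp + self.fn

    @property
    def n_neg(self) -> float:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity and odds ratio with 95% CI for one threshold."""

    sensitivity: float
    specificity: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    threshold: int | None = None
    direction: str = "score_above_is_positive"
    haldane_corrected: bool = False
    table: ConfusionTable | None = None


def confusion_at_threshold(
    scores: Sequence[int],
    labels: Sequence[bool],
    threshold: int,
    strict: bool = True,
) -> ConfusionTable:
    """Dichotomise a score at a threshold against endpoint labels.

    A subject is called positive iff ``score > threshold`` (``strict=True``)
    or ``score >= threshold`` (``strict=False``).
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length 1-d, non-empty")
    if labels.all() or (~labels).all():
        raise ValueError(
            "degenerate label vector: need at least one positive and one "
            "negative endpoint label"
        )
    calls = scores > threshold if strict else scores >= threshold
    return ConfusionTable(
        tp=float(np.sum(calls & labels)),
        fn=float(np.sum(~calls & labels)),
        fp=float(np.sum(calls & ~labels)),
        tn=float(np.sum(~calls & ~labels)),
    )


def odds_ratio(
    table: ConfusionTable,
    threshold: int | None = None,
    p_method: Literal["chi2", "fisher"] = "chi2",
) -> DiagnosticSummary:
    """Odds ratio of endpoint-positivity for test-positive vs test-negative.

    OR = (tp*tn)/(fn*fp), with Woolf's logit-scale 95% CI
    exp(ln OR +- 1.96*sqrt(1/tp + 1/fn + 1/fp + 1/tn)).  The p-value comes
    from the Pearson chi-square test on the 2x2 table (two-sided, no
    continuity correction); ``p_method="fisher"`` switches to Fisher's exact
    test (integer cells only).  If any cell is zero, 0.5 is added to all four
    cells (Haldane-Anscombe) and the result is flagged.
    """
    if table.n_pos == 0 or table.n_neg == 0 or (table.tp + table.fp) == 0 \
            or (table.fn + table.tn) == 0:
        raise ValueError("a margin of the 2x2 table is zero; OR undefined")

    sens = table.sensitivity
    spec = table.specificity

    cells = [table.tp, table.fn, table.fp, table.tn]
    haldane = any(c == 0 for c in cells)
    if haldane:
        cells = [c + 0.5 for c in cells]
    tp, fn, fp, tn = cells

    or_ = (tp * tn) / (fn * fp)
    se = math.sqrt(1 / tp + 1 / fn + 1 / fp + 1 / tn)
    ci_low = math.exp(math.log(or_) - 1.959963984540054 * se)
    ci_high = math.exp(math.log(or_) + 1.959963984540054 * se)

    contingency = np.array([[tp, fn], [fp, tn]], dtype=float)
    if p_method == "fisher":
        if not np.allclose(contingency, np.round(contingency)):
            raise ValueError("Fisher's exact test needs integer cells")
        p = stats.fisher_exact(np.round(contingency))[1]
    else:
        p = stats.chi2_contingency(contingency, correction=False)[1]

    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        odds_ratio=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        threshold=threshold,
        haldane_corrected=haldane,
        table=table,
    )


def reconstruct_table(
    sensitivity: float,
    specificity: float,
    n_pos: int,
    n_neg: int,
) -> ConfusionTable:
    """Rebuild 2x2 cells from printed sensitivity/specificity and group sizes.

    Cells are left fractional (tp = sensitivity * n_pos, etc.) so that the
    stated rates are reproduced exactly; the table is flagged
    ``reconstructed``.
    """
    if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= specificity <= 1.0:
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = sensitivity * n_pos
    tn = specificity * n_neg
    return ConfusionTable(
        tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn, reconstructed=True
    )


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve of an integer score: one point per distinct threshold.

    ``fpr``/``tpr`` are sorted by increasing FPR; ``thresholds[i]`` is the
    score value at which a non-strict (>=) call yields point i.  The leading
    (0, 0) anchor carries threshold +inf.  ``auc`` is the trapezoidal area,
    identical to the tie-corrected rank (Mann-Whitney) statistic.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def sensitivity_at(self, i: int) -> float:
        return float(self.tpr[i])

    def specificity_at(self, i: int) -> float:
        return 1.0 - float(self.fpr[i])


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC curve and AUC for a high-score-positive marker."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length 1-d, non-empty")
    if labels.all() or (~labels).all():
        raise ValueError(
            "degenerate label vector: need at least one positive and one "
            "negative endpoint label"
        )
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if not math.isclose(thr[0], np.inf):  # pragma: no cover - sklearn contract
        thr = np.concatenate([[np.inf], thr])
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn contract
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
        thr = np.concatenate([thr, [-np.inf]])
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def select_threshold(
    curve: ROCCurve,
    criterion: str = "youden",
    floor: float | None = None,
) -> int:
    """Pick an operating threshold from a ROC curve.

    ``criterion="youden"`` maximises J = sensitivity + specificity - 1;
    ``"min_sensitivity"`` maximises specificity subject to
    sensitivity >= floor; ``"min_specificity"`` maximises sensitivity
    subject to specificity >= floor.  Ties break toward the higher threshold
    (fewer positive calls).  Thresholds are for non-strict (>=) calls.
    """
    finite = np.isfinite(curve.thresholds)
    thr = curve.thresholds[finite]
    sens = curve.tpr[finite]
    spec = 1.0 - curve.fpr[finite]
    if thr.size == 0:
        raise ValueError("degenerate ROC curve: no finite thresholds")

    if criterion == "youden":
        j = sens + spec - 1.0
        best = j.max()
        idx = np.flatnonzero(np.isclose(j, best))
    elif criterion in ("min_sensitivity", "min_specificity"):
        if floor is None:
            raise ValueError(f"criterion {criterion!r} needs a floor rate")
        constrained, objective = (
            (sens, spec) if criterion == "min_sensitivity" else (spec, sens)
        )
        feasible = constrained >= floor
        if not feasible.any():
            raise ValueError(
                f"constraint infeasible: best achievable "
                f"{criterion.removeprefix('min_')} is {constrained.max():.3f} "
                f"< floor {floor}"
            )
        obj = np.where(feasible, objective, -np.inf)
        best = obj.max()
        idx = np.flatnonzero(obj == best)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    return int(thr[idx].max())
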