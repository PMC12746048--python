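"""ROC analysis over gamma passing rates.

A scenario is *positive* when its dosimetric deviation exceeds the studied
threshold (e.g. |PTV ΔDmean| > 10%). The classifier under study calls a
scenario positive when its gamma passing rate falls **below** a decision
threshold tau; a rate exactly equal to tau is called negative ("failure
modes with passing rates above the threshold were classified as negative,
while those below were classified as positive" — note this equality
convention differs from some ROC libraries). Candidate thresholds are the
distinct observed passing rates plus sentinels below the minimum and above
the maximum.

AUC is the trapezoidal area over (FPR, TPR), which equals the Mann-Whitney
probability P(rate_pos < rate_neg) + 1/2 P(tie); :func:`auc_mann_whitney`
is the direct pair-counting oracle. The optimal cutoff maximizes Youden's
J = sensitivity + specificity - 1; ties broken toward higher specificity,
then lower threshold (fewer false positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledScore",
    "RocResult",
    "RocError",
    "build_roc",
    "auc_mann_whitney",
    "summarize_group",
    "tolerance_failure_fraction",
    "round_half_up",
]


class RocError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledScore:
    """One scenario's passing rate with its binary deviation label."""

    scenario_id: str
    passing_rate_pct: float
    label: int  # 1 = positive (deviation exceeds the studied threshold)

    def __post_init__(self) -> None:
        if not (0.0 <= self.passing_rate_pct <= 100.0):
            raise RocError("passing rate must be within [0, 100]")
        if self.label not in (0, 1):
            raise RocError("label must be 0 or 1")


@dataclass
class RocResult:
    """ROC points (threshold, sensitivity, specificity, FPR), AUC and the
    Youden-optimal passing-rate cutoff."""

    points: pd.DataFrame
    auc: float
    optimal_cutoff_pct: float
    j_max: float
    sens_at_opt: float
    spec_at_opt: float


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    if not scores:
        raise RocError("empty score list")
    pos = np.array([s.passing_rate_pct for s in scores if s.label == 1], dtype=float)
    neg = np.array([s.passing_rate_pct for s in scores if s.label == 0], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise RocError("undefined ROC: need at least one positive and one negative label")
    return pos, neg


def build_roc(scores: Sequence[LabeledScore]) -> RocResult:
    """ROC curve, AUC and Youden-optimal cutoff for labeled passing rates."""
    pos, neg = _split(scores)
    rates = np.concatenate([pos, neg])
    lo, hi = rates.min(), rates.max()
    taus = np.unique(np.concatenate([rates, [lo - 1.0, hi + 1.0]]))

    rows = []
    for tau in taus:
        tp = int(np.count_nonzero(pos < tau))
        fp = int(np.count_nonzero(neg < tau))
        sens = tp / pos.size
        spec = (neg.size - fp) / neg.size
        rows.append((float(tau), sens, spec, 1.0 - spec))
    points = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "fpr"])

    order = np.argsort(points["fpr"].to_numpy(), kind="stable")
    fpr = points["fpr"].to_numpy()[order]
    tpr = points["sensitivity"].to_numpy()[order]
    auc = float(np.trapezoid(tpr, fpr))

    j = points["sensitivity"] + points["specificity"] - 1.0
    j_max = float(j.max())
    cand = points[np.isclose(j, j_max)]
    cand = cand.sort_values(["specificity", "threshold"], ascending=[False, True])
    best = cand.iloc[0]
    return RocResult(
        points=points,
        auc=auc,
        optimal_cutoff_pct=float(best["threshold"]),
        j_max=j_max,
        sens_at_opt=float(best["sensitivity"]),
        spec_at_opt=float(best["specificity"]),
    )


def auc_mann_whitney(scores: Sequence[LabeledScore]) -> float:
    """Pair-counting AUC oracle: P(rate_pos < rate_neg) + 1/2 P(tie)."""
    pos, neg = _split(scores)
    less = np.count_nonzero(pos[:, None] < neg[None, :])
    ties = np.count_nonzero(pos[:, None] == neg[None, :])
    return (less + 0.5 * ties) / (pos.size * neg.size)


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding as used in the report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_group(
    roc_results: Mapping,
    expected_criteria: Iterable | None = None,
) -> float:
    """Mean AUC over a group of criteria (e.g. the 7 global metrics at one
    deviation threshold), reported at 2 decimals.

    ``roc_results`` maps criterion keys to :class:`RocResult` or plain AUC
    floats. With ``expected_criteria``, every listed key must be present.
    """
    if expected_criteria is not None:
        missing = [c for c in expected_criteria if c not in roc_results]
        if missing:
            raise RocError(f"missing criteria in group: {missing}")
    if not roc_results:
        raise RocError("empty ROC group")
    aucs = [r.auc if isinstance(r, RocResult) else float(r) for r in roc_results.values()]
    return round_half_up(float(np.mean(aucs)), 2)


def tolerance_failure_fraction(
    rates: pd.DataFrame,
    tolerance_pct: float = 95.0,
    metric_cols: Sequence[str] = ("criterion",),
    rate_col: str = "passing_rate_pct",
) -> pd.Series:
    """Fraction of scenarios failing the tolerance passing rate, per metric.

    A scenario fails when its rate is strictly below the tolerance (a rate
    exactly at the tolerance passes). ``rates`` is the long-format table with
    one row per (scenario, metric).
    """
    if not (0.0 < tolerance_pct <= 100.0):
        raise RocError("tolerance must be in (0, 100]")
    fail = rates[rate_col] < tolerance_pct
    return fail.groupby([rates[c] for c in metric_cols]).mean()
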