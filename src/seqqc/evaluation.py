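"""Confusion-matrix metrics, enrichment summaries and group comparisons.

The QC question is asymmetric: the point of the classifier is to *enrich*
for stable ("good") acquisition sequences.  Besides accuracy, sensitivity
and specificity (positive class = good), the metrics therefore include
the good-to-poor ratio among all sequences versus among the sequences
predicted good, and the fraction of good sequences lost to the filter.

Group comparisons are kept deliberately simple: Welch's heteroscedastic
t-test for continuous summaries and the Pearson chi-square test (no
continuity correction) for 2x2 proportions.  The per-class within-session
CoV summary uses marginal means over the (tool x hemisphere x session)
cells with the standard error taken across session-level means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionTable",
    "confusion",
    "metrics",
    "welch_t",
    "chi2_2x2",
    "marginal_cov_means",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts with "good" as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(
        cls, y_true: Sequence, y_pred: Sequence, *, positive: str = "good"
    ) -> "ConfusionTable":
        t = np.asarray(y_true)
        p = np.asarray(y_pred)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must have equal length")
        pos_t = t == positive
        pos_p = p == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


def confusion(
    y_true: Sequence, y_pred: Sequence, *, positive: str = "good"
) -> ConfusionTable:
    """Confusion table of predicted vs true labels (positive = good)."""
    return ConfusionTable.from_labels(y_true, y_pred, positive=positive)


def metrics(table: ConfusionTable) -> dict:
    """Classification and enrichment summaries of a confusion table.

    Returns accuracy/sensitivity/specificity in percent, the good-to-poor
    ratio among all cases (``ratio_all``) and among the cases predicted
    good (``ratio_pred_good``), and the percentage of good cases lost by
    the filter (``lost_good_pct``).  A metric with a zero denominator is
    returned as NaN and listed under ``"undefined"``.
    """
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    out: dict = {}
    undefined: list[str] = []

    def _ratio(name: str, num: float, den: float, scale: float = 1.0) -> None:
        if den == 0:
            out[name] = float("nan")
            undefined.append(name)
        else:
            out[name] = scale * num / den

    _ratio("accuracy_pct", tp + tn, table.total, 100.0)
    _ratio("sensitivity_pct", tp, tp + fn, 100.0)
    _ratio("specificity_pct", tn, tn + fp, 100.0)
    _ratio("ratio_all", tp + fn, fp + tn)
    _ratio("ratio_pred_good", tp, fp)
    _ratio("lost_good_pct", fn, tp + fn, 100.0)
    out["undefined"] = undefined
    return out


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's heteroscedastic two-sample t-test.

    Returns ``(t, df, p)`` with the Welch statistic, Satterthwaite degrees
    of freedom and the two-sided p-value.  If both groups have zero
    variance and equal means the comparison is vacuous; by convention
    ``(0, n_a + n_b - 2, 1)`` is returned.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1) / x.size
    vy = y.var(ddof=1) / y.size
    if vx + vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square test of independence for a 2x2 table.

    No continuity correction, 1 degree of freedom.  Zero row or column
    margins make the expected counts degenerate and raise an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in the 2x2 table")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


def marginal_cov_means(
    stability: pd.DataFrame, session_labels: pd.Series
) -> pd.DataFrame:
    """Per-class mean within-session CoV with standard errors.

    ``stability`` is the long per-(tool, hemisphere, session) table with a
    ``cov_pct`` column; ``session_labels`` maps session id to the CART
    class.  Each session is first collapsed to its mean CoV across the
    (tool x hemisphere) cells; the class mean and the standard error of
    those session-level means are then reported per class.
    """
    if not {"session_id", "cov_pct"} <= set(stability.columns):
        raise ValueError("stability table must have session_id and cov_pct columns")
    labels = pd.Series(session_labels)
    session_means = stability.groupby("session_id")["cov_pct"].mean()
    aligned = labels.reindex(session_means.index)
    if aligned.isna().any():
        raise ValueError("every session in the stability table needs a class label")
    rows = []
    for cls, grp in session_means.groupby(aligned):
        n = int(grp.size)
        sd = float(grp.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "label": cls,
                "mean_cov_pct": float(grp.mean()),
                "se_cov_pct": sd / np.sqrt(n) if n > 0 else float("nan"),
                "n_sessions": n,
            }
        )
    if len(rows) < 2:
        raise ValueError("both classes must be non-empty")
    return pd.DataFrame(rows).set_index("label")
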