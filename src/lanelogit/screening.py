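"""Pearson-correlation collinearity screen over dummy design columns.

Candidate dummy columns that are strongly pairwise correlated cannot enter
the logit together.  The screen computes the Pearson correlation matrix of
all non-intercept columns, flags pairs with |r| above a threshold, and
resolves each flagged pair deterministically: the member with the larger
absolute point-biserial correlation with the outcome is retained (ties break
in column order).  Every decision is logged so the variable-selection step
is auditable.  The default cutoff |r| > 0.7 is the usual rule of thumb for
"severe" collinearity; it is a configuration knob, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import DesignMatrix, subset_columns

__all__ = ["ScreeningReport", "pearson_matrix", "screen_variables", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.7


@dataclass
class ScreeningReport:
    correlations: pd.DataFrame
    threshold: float
    flagged: list[tuple[str, str, float]]
    retained: list[str]
    dropped: list[str]
    decisions: list[str] = field(default_factory=list)

    def retained_design(self, dm: DesignMatrix) -> DesignMatrix:
        return subset_columns(dm, self.retained)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "flagged": [[a, b, r] for a, b, r in self.flagged],
            "retained": self.retained,
            "dropped": self.dropped,
            "decisions": self.decisions,
            "correlations": self.correlations.round(6).to_dict(),
        }


def pearson_matrix(dm: DesignMatrix) -> pd.DataFrame:
    """Pearson correlations of all non-intercept design columns."""
    if dm.n < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    labels = dm.columns[1:]
    X = dm.X[:, 1:]
    sd = X.std(axis=0)
    zero = [labels[j] for j in np.flatnonzero(sd == 0)]
    if zero:
        raise ValueError(f"zero-variance design columns: {zero}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=labels, columns=labels)


def screen_variables(
    dm: DesignMatrix, y: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ScreeningReport:
    """Resolve collinear column pairs against the outcome association.

    Iteratively, among retained columns, the most correlated flagged pair is
    resolved by dropping the member whose |corr(column, y)| is smaller; on a
    tie the earlier column (design order) wins.  The result is idempotent:
    no retained pair exceeds the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    corr = pearson_matrix(dm)
    labels = list(corr.columns)
    R = corr.to_numpy()
    # point-biserial = plain Pearson correlation of a dummy with binary y
    ysd = y.std()
    if ysd == 0:
        outcome_corr = np.zeros(len(labels))
    else:
        X = dm.X[:, 1:]
        outcome_corr = np.array(
            [np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])]
        )

    flagged = [
        (labels[j], labels[k], float(R[j, k]))
        for j in range(len(labels))
        for k in range(j + 1, len(labels))
        if abs(R[j, k]) > threshold
    ]

    retained = list(range(len(labels)))
    dropped: list[int] = []
    decisions: list[str] = []
    while True:
        pairs = [
            (abs(R[j, k]), j, k)
            for i1, j in enumerate(retained)
            for k in retained[i1 + 1 :]
            if abs(R[j, k]) > threshold
        ]
        if not pairs:
            break
        _, j, k = max(pairs, key=lambda t: (t[0], -t[1], -t[2]))
        cj, ck = abs(outcome_corr[j]), abs(outcome_corr[k])
        loser = k if (cj > ck or np.isclose(cj, ck)) else j
        winner = j if loser == k else k
        retained.remove(loser)
        dropped.append(loser)
        decisions.append(
            f"|r({labels[j]}, {labels[k]})| = {abs(R[j, k]):.4f} > {threshold}: "
            f"kept {labels[winner]!r} (|r_y| = {abs(outcome_corr[winner]):.4f}), "
            f"dropped {labels[loser]!r} (|r_y| = {abs(outcome_corr[loser]):.4f})"
        )

    return ScreeningReport(
        correlations=corr,
        threshold=threshold,
        flagged=flagged,
        retained=[labels[j] for j in sorted(retained)],
        dropped=[labels[j] for j in sorted(dropped)],
        decisions=decisions,
    )
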