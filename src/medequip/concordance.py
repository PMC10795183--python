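"""Cross-method agreement statistics.

When several ranking methods score the same equipment fleet, Kendall's
coefficient of concordance W measures how consistently the methods'
scores order each other across devices.  Following the "k related
samples" convention, each piece of equipment is a block that ranks the k
method scores; W = 12 S / (n^2 (k^3 - k)) with S the squared deviation of
the treatment rank sums from their mean, and chi^2 = n (k - 1) W is
referred to a chi-square distribution with k - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .core import DecisionMatrix, ValidationError

__all__ = ["ConcordanceResult", "kendall_w", "method_summaries", "pearson_report"]


@dataclass
class ConcordanceResult:
    method_tags: list[str]
    block_ids: list[str]
    rank_matrix: pd.DataFrame          # blocks x treatments, tie-averaged ranks
    rank_averages: pd.Series
    medians: pd.Series
    W: float
    chi2: float
    df: int
    p_value: float

    def as_frame(self) -> pd.DataFrame:
        """Per-method summary table (rank average, median, W, chi2, p)."""
        out = pd.DataFrame(
            {"rank_average": self.rank_averages, "median": self.medians}
        )
        out["W"] = self.W
        out["chi2"] = self.chi2
        out["p"] = self.p_value
        return out


def _as_frame(scores) -> pd.DataFrame:
    df = pd.DataFrame(scores)
    if df.isna().any().any():
        raise ValidationError("missing score in concordance input")
    return df.astype(float)


def kendall_w(
    scores,
    tie_correction: bool = False,
    transpose: bool = False,
) -> ConcordanceResult:
    """Kendall's W over a blocks x treatments score table.

    Rows are blocks (equipment), columns treatments (methods); each block's
    scores are ranked ascending with ties averaged.  ``transpose=True``
    swaps the roles (methods rank the equipment instead).
    ``tie_correction`` subtracts the usual tie term from the denominator.
    """
    df = _as_frame(scores)
    if transpose:
        df = df.T
    n, k = df.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >=2 blocks and >=2 treatments, got {df.shape}")

    ranks = df.apply(lambda row: rankdata(row), axis=1, result_type="expand")
    ranks.columns = df.columns
    R = ranks.sum(axis=0).to_numpy()
    S = float(((R - n * (k + 1) / 2) ** 2).sum())
    denom = n ** 2 * (k ** 3 - k)
    if tie_correction:
        T = 0.0
        for _, row in ranks.iterrows():
            _, counts = np.unique(row.to_numpy(), return_counts=True)
            T += float((counts ** 3 - counts).sum())
        denom -= n * T
    if denom <= 0:
        raise ValidationError("degenerate rank table (all scores tied)")
    W = 12.0 * S / denom
    stat = n * (k - 1) * W
    dof = k - 1
    return ConcordanceResult(
        method_tags=[str(c) for c in df.columns],
        block_ids=[str(i) for i in df.index],
        rank_matrix=ranks,
        rank_averages=ranks.mean(axis=0),
        medians=df.median(axis=0),
        W=W,
        chi2=stat,
        df=dof,
        p_value=float(chi2_sf(stat, dof)),
    )


def chi2_sf(stat: float, dof: int) -> float:
    return float(chi2.sf(stat, dof))


def method_summaries(scores) -> pd.DataFrame:
    """Within-block rank averages and score medians per method."""
    res = kendall_w(scores)
    return pd.DataFrame(
        {"rank_average": res.rank_averages, "median": res.medians}
    )


def pearson_report(matrix: DecisionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between indicator columns.

    Zero-variance columns yield NaN rows/columns (flagged, not an error) so
    the rest of the report survives a degenerate indicator.
    """
    df = matrix.values if isinstance(matrix, DecisionMatrix) else pd.DataFrame(matrix)
    if df.shape[0] < 3:
        raise ValidationError("need at least three rows for correlations")
    R = df.corr(method="pearson")
    for col in df.columns:
        if df[col].std(ddof=1) == 0:
            R.loc[col, :] = np.nan
            R.loc[:, col] = np.nan
    valid = [c for c in df.columns if df[c].std(ddof=1) > 0]
    for c in valid:
        R.loc[c, c] = 1.0
    return R
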