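"""Objective indicator weighting by principal component analysis.

The decision matrix is direction-aware min-max normalized, the indicator
correlation matrix is eigendecomposed, and a number of leading components
is retained (by cumulative explained variance, Kaiser rule, or a fixed
count).  Each indicator's composite score is the variance-weighted average
of the absolute values of its loadings on the retained components,

    score_i = sum_{j<=p} a_j |c_ij| / sum_{j<=p} a_j ,

with a_j = lambda_j / n the variance share of component j; weights are the
scores renormalized over indicators.  Absolute loadings make the weights
invariant to the arbitrary sign of each eigenvector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BENEFIT, COST, DecisionMatrix, ValidationError, WeightVector

__all__ = [
    "PcaResult",
    "minmax_normalize",
    "correlation_matrix",
    "eigendecompose_and_retain",
    "pca_scores_and_weights",
    "pca_weights",
]


@dataclass
class PcaResult:
    normalized_matrix: pd.DataFrame
    correlation_matrix: pd.DataFrame
    eigenvalues: np.ndarray                # descending
    loadings: pd.DataFrame                 # indicators x retained components
    variance_contribution: np.ndarray      # a_j for all components
    cumulative_contribution: float         # b_p over retained components
    n_retained: int
    indicator_scores: np.ndarray
    weights: WeightVector


def minmax_normalize(matrix: DecisionMatrix) -> pd.DataFrame:
    """Direction-aware min-max scaling of each indicator column to [0, 1].

    Benefit columns map best (largest) raw values to 1; cost columns map
    best (smallest) raw values to 1, so after scaling, 1 always means
    "supports replacement most".  A constant column carries no ordering
    information and is set to 0.5 everywhere, with a warning.
    """
    df = matrix.values.astype(float)
    out = {}
    for col, d in matrix.directions.items():
        x = df[col]
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(
                f"indicator {col} is constant across equipment; "
                "normalized to 0.5",
                stacklevel=2,
            )
            out[col] = pd.Series(0.5, index=x.index)
        elif d == BENEFIT:
            out[col] = (x - lo) / (hi - lo)
        elif d == COST:
            out[col] = (hi - x) / (hi - lo)
        else:  # pragma: no cover - guarded by IndicatorDefinition
            raise ValidationError(f"unknown direction {d!r}")
    return pd.DataFrame(out, index=df.index)[df.columns]


def correlation_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between indicator columns (unit diagonal)."""
    if normalized.shape[0] < 3:
        raise ValidationError(
            "need at least three equipment rows for a meaningful correlation"
        )
    std = normalized.std(ddof=1)
    if (std == 0).any():
        bad = list(std.index[std == 0])
        raise ValidationError(f"zero-variance indicator columns: {bad}")
    R = normalized.corr(method="pearson")
    np.fill_diagonal(R.values, 1.0)
    return R


def eigendecompose_and_retain(
    R: pd.DataFrame | np.ndarray,
    retention: str = "cumulative:0.85",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigenpairs of the correlation matrix, sorted by descending eigenvalue.

    ``retention`` selects how many components to keep:

    - ``"cumulative:T"`` — smallest p whose variance shares sum to >= T
      (default threshold 0.85);
    - ``"kaiser"`` — components with eigenvalue >= 1;
    - ``"fixed:p"`` — exactly p components.

    Returns ``(eigenvalues, eigenvectors_as_columns, p)``.
    """
    A = np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)  # numerical negatives on rank-deficient R

    shares = evals / evals.sum()
    kind, _, arg = retention.partition(":")
    if kind == "cumulative":
        thr = float(arg) if arg else 0.85
        p = int(np.searchsorted(np.cumsum(shares), thr - 1e-12) + 1)
        p = min(p, len(evals))
    elif kind == "kaiser":
        p = max(1, int((evals >= 1.0).sum()))
    elif kind == "fixed":
        p = int(arg)
        if not 1 <= p <= len(evals):
            raise ValidationError(f"fixed retention {p} outside 1..{len(evals)}")
    else:
        raise ValidationError(f"unknown retention policy {retention!r}")
    return evals, evecs, p


def pca_scores_and_weights(
    loadings,
    variance_contribution,
    p: int | None = None,
    indicator_ids=None,
) -> tuple[np.ndarray, WeightVector]:
    """Composite indicator scores and normalized weights from loadings.

    ``loadings`` is indicators x components, ``variance_contribution`` the
    per-component variance shares; only the first ``p`` columns are used
    (all, if omitted).
    """
    C = np.asarray(loadings, dtype=float)
    a = np.asarray(variance_contribution, dtype=float)
    if p is None:
        p = C.shape[1]
    if p < 1 or p > C.shape[1] or p > a.size:
        raise ValidationError(f"cannot retain {p} of {C.shape[1]} components")
    C, a = np.abs(C[:, :p]), a[:p]
    scores = C @ a / a.sum()
    if not (scores > 0).any():
        raise ValidationError("all-zero loadings: scores undefined")
    if indicator_ids is None:
        indicator_ids = [f"I{i+1}" for i in range(C.shape[0])]
    wv = WeightVector(
        indicator_ids=list(indicator_ids),
        weights=scores / scores.sum(),
        method_tag="pca",
    )
    return scores, wv


def pca_weights(
    matrix: DecisionMatrix,
    retention: str = "cumulative:0.85",
    normalization: str = "minmax",
) -> PcaResult:
    """Full objective-weighting chain: normalize, correlate, retain, score.

    ``normalization`` is ``"minmax"`` (direction-aware, the default) or
    ``"zscore"`` (plain standardization; correlations are identical, only
    the stored normalized matrix differs).
    """
    if normalization == "minmax":
        Z = minmax_normalize(matrix)
    elif normalization == "zscore":
        df = matrix.values.astype(float)
        std = df.std(ddof=1)
        if (std == 0).any():
            raise ValidationError(
                f"zero-variance columns: {list(std.index[std == 0])}"
            )
        Z = (df - df.mean()) / std
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")

    R = correlation_matrix(Z)
    evals, evecs, p = eigendecompose_and_retain(R, retention)
    shares = evals / evals.sum()
    # component loadings: eigenvector scaled by sqrt(eigenvalue)
    load = evecs[:, :p] * np.sqrt(evals[:p])
    scores, wv = pca_scores_and_weights(
        load, shares, p, indicator_ids=list(matrix.indicator_ids)
    )
    return PcaResult(
        normalized_matrix=Z,
        correlation_matrix=R,
        eigenvalues=evals,
        loadings=pd.DataFrame(
            load,
            index=matrix.indicator_ids,
            columns=[f"PC{j+1}" for j in range(p)],
        ),
        variance_contribution=shares,
        cumulative_contribution=float(shares[:p].sum()),
        n_retained=p,
        indicator_scores=scores,
        weights=wv,
    )
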