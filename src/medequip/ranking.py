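"""Replacement-priority ranking: GRA-TOPSIS fusion, plain GRA, plain
TOPSIS, and VIKOR.

All methods start from the direction-aware min-max normalized matrix z
(1 = supports replacement most is *not* the convention here; after the
direction adjustment, 1 means the device performs best on that criterion,
so the *negative* ideal — the all-worst profile — is the replacement
ideal).  The fusion method weights z (S = w * z), measures each device
twice against the two ideal profiles:

- Euclidean distances d+/d- to the positive/negative ideal (TOPSIS view),
- gray relational degrees l+/l- of shape similarity to them (GRA view),

normalizes each of the four measures by its maximum (D, L), and blends
them into the replacement decision factor

    T+ = a1 D+ + a2 L-,   T- = a1 D- + a2 L+,   xi = T+ / (T+ + T-).

Under this (default, "priority") orientation a device far from the best
profile and similar in shape to the worst one gets a large xi: replace it
first.  The mirrored ("proximity") orientation swaps the roles and ranks
well-performing devices highest; the two decision factors are exact
complements (xi_priority + xi_proximity = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import DecisionMatrix, RankingResult, ValidationError, WeightVector
from .pca_weights import minmax_normalize

__all__ = [
    "FusionDiagnostics",
    "weighted_normalized_matrix",
    "euclidean_distances",
    "gray_coefficients",
    "gray_degrees",
    "normalize_measures",
    "fuse",
    "rank_gra_topsis",
    "rank_gra",
    "rank_topsis",
    "rank_vikor",
]


@dataclass
class FusionDiagnostics:
    weighted_matrix: pd.DataFrame
    ideal_positive: np.ndarray
    ideal_negative: np.ndarray
    d_pos: np.ndarray
    d_neg: np.ndarray
    gray_pos: np.ndarray                  # H+ coefficients, m x n
    gray_neg: np.ndarray
    l_pos: np.ndarray
    l_neg: np.ndarray
    D_pos: np.ndarray
    D_neg: np.ndarray
    L_pos: np.ndarray
    L_neg: np.ndarray
    T_pos: np.ndarray
    T_neg: np.ndarray
    xi: np.ndarray
    rho: float
    alpha1: float
    alpha2: float
    orientation: str


def _priority_ranks(scores: np.ndarray, descending: bool = True) -> np.ndarray:
    """Rank 1 = top priority; ties averaged."""
    return rankdata(-scores if descending else scores, method="average")


def weighted_normalized_matrix(
    matrix: DecisionMatrix, weights: WeightVector
) -> pd.DataFrame:
    """S = w * z: direction-adjusted normalized matrix scaled by weights."""
    z = minmax_normalize(matrix)
    w = weights.aligned_to(matrix.indicator_ids)
    return z * w


def euclidean_distances(S: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances of each row to the column-max (d+) and column-min (d-) profiles."""
    A = np.asarray(S, dtype=float)
    if A.shape[0] < 2:
        raise ValidationError("need at least two equipment rows")
    s_pos, s_neg = A.max(axis=0), A.min(axis=0)
    d_pos = np.sqrt(((A - s_pos) ** 2).sum(axis=1))
    d_neg = np.sqrt(((A - s_neg) ** 2).sum(axis=1))
    return d_pos, d_neg


def gray_coefficients(
    S: pd.DataFrame | np.ndarray, rho: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Gray relational coefficient matrices against the two ideal profiles.

    For the positive ideal, with Delta = |s+ - s_ij| and global extremes
    Delta_min/Delta_max over the whole matrix:

        h_ij = (Delta_min + rho Delta_max) / (Delta_ij + rho Delta_max).

    The resolution factor rho in (0, 1] controls contrast; at the customary
    rho = 0.5 and Delta_min = 0 the coefficients live in [1/3, 1].
    """
    if not 0 < rho <= 1:
        raise ValidationError(f"resolution factor rho={rho} outside (0, 1]")
    A = np.asarray(S, dtype=float)
    out = []
    for ref in (A.max(axis=0), A.min(axis=0)):
        delta = np.abs(ref - A)
        dmin, dmax = delta.min(), delta.max()
        if dmax == 0:
            warnings.warn(
                "all equipment rows identical; gray coefficients set to 1",
                stacklevel=2,
            )
            out.append(np.ones_like(delta))
        else:
            out.append((dmin + rho * dmax) / (delta + rho * dmax))
    return out[0], out[1]


def gray_degrees(
    H_pos: np.ndarray,
    H_neg: np.ndarray,
    weights: WeightVector | np.ndarray,
    indicator_ids=None,
    scheme: str = "weights",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-equipment gray relational degrees: aggregate coefficients over
    indicators.

    ``scheme="weights"`` takes the weighted mean with the indicator
    weights (weighting thus enters both the matrix scaling and the
    aggregation); ``"uniform"`` takes the plain row mean.  A constant
    prefactor would cancel in the later max-normalization, so none is
    applied.
    """
    if scheme == "uniform":
        return H_pos.mean(axis=1), H_neg.mean(axis=1)
    if scheme != "weights":
        raise ValidationError(f"unknown gray-degree scheme {scheme!r}")
    if isinstance(weights, WeightVector):
        w = weights.aligned_to(indicator_ids) if indicator_ids is not None \
            else weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    return H_pos @ w, H_neg @ w


def normalize_measures(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Scale each measure vector by its own maximum (so each peaks at 1)."""
    out = []
    for v in vectors:
        v = np.asarray(v, dtype=float)
        top = v.max()
        if top <= 0:
            raise ValidationError("measure vector has no positive maximum")
        out.append(v / top)
    return tuple(out)


def fuse(
    D_pos: np.ndarray,
    D_neg: np.ndarray,
    L_pos: np.ndarray,
    L_neg: np.ndarray,
    alpha1: float = 0.5,
    alpha2: float = 0.5,
    orientation: str = "priority",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blend normalized distances and relational degrees into the decision
    factor xi = T+ / (T+ + T-).

    ``orientation="priority"`` (default): T+ = a1 D+ + a2 L-, T- = a1 D- +
    a2 L+; large xi = replace sooner.  ``"proximity"`` swaps the two, so
    large xi = performs best; the two xi values are complementary.
    """
    if not np.isclose(alpha1 + alpha2, 1.0) or not (0 < alpha1 < 1):
        raise ValidationError(
            f"preferences must satisfy alpha1+alpha2=1 in (0,1), "
            f"got {alpha1}, {alpha2}"
        )
    D_pos, D_neg, L_pos, L_neg = map(np.asarray, (D_pos, D_neg, L_pos, L_neg))
    if orientation == "priority":
        T_pos = alpha1 * D_pos + alpha2 * L_neg
        T_neg = alpha1 * D_neg + alpha2 * L_pos
    elif orientation == "proximity":
        T_pos = alpha1 * D_neg + alpha2 * L_pos
        T_neg = alpha1 * D_pos + alpha2 * L_neg
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    total = T_pos + T_neg
    if np.any(total == 0):
        raise ValidationError("T+ + T- is zero for some equipment")
    return T_pos / total, T_pos, T_neg


def rank_gra_topsis(
    matrix: DecisionMatrix,
    weights: WeightVector,
    rho: float = 0.5,
    alpha1: float = 0.5,
    alpha2: float = 0.5,
    orientation: str = "priority",
    gray_degree_weighting: str = "weights",
) -> RankingResult:
    """Full GRA-TOPSIS fusion ranking of a decision matrix."""
    S = weighted_normalized_matrix(matrix, weights)
    A = S.to_numpy()
    d_pos, d_neg = euclidean_distances(A)
    H_pos, H_neg = gray_coefficients(A, rho=rho)
    w = weights.aligned_to(matrix.indicator_ids)
    l_pos, l_neg = gray_degrees(H_pos, H_neg, w, scheme=gray_degree_weighting)
    D_pos, D_neg, L_pos, L_neg = normalize_measures(d_pos, d_neg, l_pos, l_neg)
    xi, T_pos, T_neg = fuse(D_pos, D_neg, L_pos, L_neg,
                            alpha1=alpha1, alpha2=alpha2,
                            orientation=orientation)
    diag = FusionDiagnostics(
        weighted_matrix=S,
        ideal_positive=A.max(axis=0),
        ideal_negative=A.min(axis=0),
        d_pos=d_pos, d_neg=d_neg,
        gray_pos=H_pos, gray_neg=H_neg,
        l_pos=l_pos, l_neg=l_neg,
        D_pos=D_pos, D_neg=D_neg, L_pos=L_pos, L_neg=L_neg,
        T_pos=T_pos, T_neg=T_neg, xi=xi,
        rho=rho, alpha1=alpha1, alpha2=alpha2, orientation=orientation,
    )
    result = RankingResult(
        equipment_ids=matrix.equipment_ids,
        method_tag="gra_topsis",
        scores=xi,
        ranks=_priority_ranks(xi, descending=(orientation == "priority")),
        diagnostics={
            "D_pos": list(D_pos), "D_neg": list(D_neg),
            "L_pos": list(L_pos), "L_neg": list(L_neg),
            "T_pos": list(T_pos), "T_neg": list(T_neg),
        },
    )
    result.fusion = diag  # full intermediates for inspection
    return result


def rank_gra(
    matrix: DecisionMatrix,
    weights: WeightVector,
    rho: float = 0.5,
) -> RankingResult:
    """Plain gray relational ranking.

    The reference profile is the replacement ideal — the all-worst row of
    the direction-adjusted normalized matrix — and the score is the
    weighted gray relational degree to it, so the device most similar in
    shape to the worst profile is replaced first.
    """
    z = minmax_normalize(matrix).to_numpy()
    _, H_neg = gray_coefficients(z, rho=rho)
    w = weights.aligned_to(matrix.indicator_ids)
    score = H_neg @ w
    return RankingResult(
        equipment_ids=matrix.equipment_ids,
        method_tag="gra",
        scores=score,
        ranks=_priority_ranks(score),
        diagnostics={"gray_degree_neg": list(score)},
    )


def rank_topsis(
    matrix: DecisionMatrix,
    weights: WeightVector,
) -> RankingResult:
    """Plain TOPSIS in the replacement-priority reading.

    Relative closeness to the *negative* (all-worst) ideal,
    d+ / (d+ + d-): the worst-performing device scores highest and is
    replaced first.
    """
    S = weighted_normalized_matrix(matrix, weights).to_numpy()
    d_pos, d_neg = euclidean_distances(S)
    total = d_pos + d_neg
    if np.any(total == 0):
        raise ValidationError("identical equipment rows: TOPSIS undefined")
    score = d_pos / total
    return RankingResult(
        equipment_ids=matrix.equipment_ids,
        method_tag="topsis",
        scores=score,
        ranks=_priority_ranks(score),
        diagnostics={"d_pos": list(d_pos), "d_neg": list(d_neg)},
    )


def rank_vikor(
    matrix: DecisionMatrix,
    weights: WeightVector,
    v: float = 0.5,
) -> RankingResult:
    """VIKOR compromise ranking on the replacement-need scale.

    Criteria are mapped to replacement need u = 1 - z (z the
    direction-adjusted normalized matrix), so the device with the greatest
    need is the VIKOR "best".  Group utility S_i, individual regret R_i and
    the compromise index

        Q_i = v (S_i - S*) / (S- - S*) + (1 - v) (R_i - R*) / (R- - R*)

    follow the standard construction; ranking is ascending in Q, so Q = 0
    marks the device to replace first.
    """
    if not 0 <= v <= 1:
        raise ValidationError(f"v={v} outside [0, 1]")
    z = minmax_normalize(matrix).to_numpy()
    u = 1.0 - z                                 # replacement-need scale
    w = weights.aligned_to(matrix.indicator_ids)
    f_best, f_worst = u.max(axis=0), u.min(axis=0)
    span = f_best - f_worst
    with np.errstate(invalid="ignore", divide="ignore"):
        term = w * (f_best - u) / span
    term[:, span == 0] = 0.0                    # constant criterion: no regret
    S = term.sum(axis=1)
    R = term.max(axis=1)

    def _scale(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    if S.max() == S.min() and R.max() == R.min():
        warnings.warn("all equipment equivalent; VIKOR Q set to 0",
                      stacklevel=2)
    Q = v * _scale(S) + (1 - v) * _scale(R)
    return RankingResult(
        equipment_ids=matrix.equipment_ids,
        method_tag="vikor",
        scores=Q,
        ranks=_priority_ranks(Q, descending=False),
        diagnostics={"S": list(S), "R": list(R), "Q": list(Q)},
    )
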