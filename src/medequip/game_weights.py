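"""Game-theoretic combination of candidate weight vectors.

Given L candidate weightings W_1..W_L of the same indicators (here:
expert-derived COWA weights and data-derived PCA weights), the combined
vector W = sum_k lambda_k W_k is chosen to minimize the total squared
deviation sum_k ||W - W_k||^2 — the equilibrium at which no single
weighting is favoured more than the data demands.  Setting the gradient to
zero gives the linear system

    sum_k (W_j . W_k) lambda_k = W_j . W_j ,   j = 1..L,

whose solution is normalized to sum to one (negative coefficients are
clipped first so the result stays a convex combination and weight
non-negativity survives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ValidationError, WeightVector

__all__ = ["GameCombination", "combine"]


@dataclass
class GameCombination:
    input_weights: list[WeightVector]
    raw_coefficients: np.ndarray          # lambda, unnormalized solution
    normalized_coefficients: np.ndarray   # lambda*, sums to 1
    combined: WeightVector


def combine(weight_vectors: Sequence[WeightVector]) -> GameCombination:
    """Optimal convex combination of two or more weight vectors."""
    if len(weight_vectors) < 2:
        raise ValidationError("need at least two weight vectors to combine")
    ids = list(weight_vectors[0].indicator_ids)
    W = np.empty((len(weight_vectors), len(ids)))
    for k, wv in enumerate(weight_vectors):
        W[k] = wv.aligned_to(ids)

    L = W.shape[0]
    A = W @ W.T                       # A[j, k] = W_j . W_k
    b = np.einsum("kj,kj->k", W, W)   # b[j]   = W_j . W_j
    try:
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        lam = np.linalg.solve(A, b)
        if not np.all(np.isfinite(lam)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        warnings.warn(
            "combination system is singular (identical or collinear weight "
            "vectors); falling back to the equal-coefficient mix",
            stacklevel=2,
        )
        lam = np.full(L, 1.0 / L)

    if np.isclose(lam.sum(), 0.0):
        warnings.warn("degenerate coefficients; using equal mix", stacklevel=2)
        lam = np.full(L, 1.0 / L)
    lam_star = lam / lam.sum()
    if (lam_star < -1e-9).any():
        warnings.warn(
            f"negative combination coefficients {lam_star} clipped to keep "
            "the result a convex combination",
            stacklevel=2,
        )
    lam_star = np.clip(lam_star, 0.0, None)
    lam_star = lam_star / lam_star.sum()

    combined = WeightVector(
        indicator_ids=ids,
        weights=lam_star @ W,
        method_tag="game",
    )
    return GameCombination(
        input_weights=list(weight_vectors),
        raw_coefficients=lam,
        normalized_coefficients=lam_star,
        combined=combined,
    )
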