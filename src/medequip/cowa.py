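"""Expert-opinion weighting with the combined ordered weighted averaging
(COWA) operator.

Each indicator is scored 0-10 by a panel of experts.  Scores are sorted in
descending order and averaged with binomial position weights
``theta_{j+1} = C(n-1, j) / 2^(n-1)``, which peak in the middle of the
sorted list: the most extreme opinions on either side get the smallest
weight, damping outlier experts without discarding them.  The per-indicator
aggregates (absolute weights) are then normalized across indicators to a
weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .core import ExpertScorePanel, ValidationError, WeightVector

__all__ = ["CowaResult", "position_weights", "absolute_weight", "cowa_weights"]


@dataclass
class CowaResult:
    position_weights: np.ndarray          # theta, length n_experts
    absolute_weights: np.ndarray          # omega-bar, one per indicator
    contributions: np.ndarray             # indicators x experts, theta_j * b_j
    relative_weights: WeightVector


def position_weights(n_experts: int) -> np.ndarray:
    """Binomial position weights for a sorted list of ``n_experts`` scores.

    theta_{j+1} = C(n-1, j) / 2^(n-1) for j = 0..n-1; symmetric and summing
    to one.
    """
    if n_experts < 1:
        raise ValidationError("need at least one expert")
    n = n_experts
    return np.array([comb(n - 1, j) for j in range(n)], dtype=float) / 2 ** (n - 1)


def absolute_weight(scores) -> tuple[float, np.ndarray]:
    """Position-weighted aggregate of one indicator's expert scores.

    Scores are sorted descending (stable, so the exposed contribution
    vector is reproducible) and multiplied elementwise by the position
    weights.  Returns ``(omega_bar, contributions)`` where ``omega_bar``
    is the sum of the contributions — a convex combination of the scores,
    so always within their range.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("empty score list")
    if (scores < 0).any() or (scores > 10).any():
        raise ValidationError("scores must lie in [0, 10]")
    b = np.sort(scores, kind="stable")[::-1]
    theta = position_weights(b.size)
    contributions = theta * b
    return float(contributions.sum()), contributions


def cowa_weights(panel: ExpertScorePanel) -> CowaResult:
    """Indicator weights from an expert panel: aggregate, then normalize."""
    if len(panel.indicator_ids) < 2:
        raise ValidationError("need at least two indicators to weight")
    omega_bar = np.empty(len(panel.indicator_ids))
    contribs = np.empty((len(panel.indicator_ids), panel.n_experts))
    for i, col in enumerate(panel.indicator_ids):
        omega_bar[i], contribs[i] = absolute_weight(panel.scores[col].to_numpy())
    total = omega_bar.sum()
    if total <= 0:
        raise ValidationError("degenerate panel: all aggregate scores zero")
    wv = WeightVector(
        indicator_ids=list(panel.indicator_ids),
        weights=omega_bar / total,
        method_tag="cowa",
    )
    return CowaResult(
        position_weights=position_weights(panel.n_experts),
        absolute_weights=omega_bar,
        contributions=contribs,
        relative_weights=wv,
    )
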