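"""The nine replacement-priority indicators, computed from equipment logs.

Workload indicators charge each exam its mean duration ``tau`` plus a fixed
per-exam preparation allowance (2 minutes by default), so the work
saturation of a device that ran N exams while powered on for ``eta_b``
minutes is ``(tau + prep) * N / eta_b``.  Timing indicators (X21, X22) are
computed from the raw exam log; everything else comes from the period
profile.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DecisionMatrix,
    EquipmentProfile,
    ExamRecord,
    IndicatorDefinition,
    INDICATOR_IDS,
    ValidationError,
)

__all__ = [
    "operating_saturation",
    "equipment_utilization",
    "work_intensity",
    "mean_wait",
    "mean_interval",
    "life_index",
    "failure_count",
    "cost_benefit_ratio",
    "payback_period",
    "indicator_vector",
    "build_decision_matrix",
]

logger = logging.getLogger(__name__)


def operating_saturation(profile: EquipmentProfile) -> float:
    """X11: exam workload (incl. preparation) over powered-on minutes."""
    if profile.exam_count == 0:
        return 0.0
    if profile.power_on_minutes <= 0:
        raise ValidationError(
            f"{profile.equipment_id}: power_on_minutes must be positive "
            "to compute work saturation"
        )
    load = (profile.mean_exam_minutes + profile.prep_minutes) * profile.exam_count
    return load / profile.power_on_minutes


def equipment_utilization(profile: EquipmentProfile) -> float:
    """X12: working minutes over powered-on minutes, in [0, 1]."""
    if profile.power_on_minutes <= 0:
        raise ValidationError(
            f"{profile.equipment_id}: power_on_minutes must be positive"
        )
    return profile.working_minutes / profile.power_on_minutes


def work_intensity(profile: EquipmentProfile) -> float:
    """X13: exam workload (incl. preparation) over rated working minutes."""
    if profile.exam_count == 0:
        return 0.0
    if profile.rated_minutes <= 0:
        raise ValidationError(
            f"{profile.equipment_id}: rated_minutes must be positive"
        )
    load = (profile.mean_exam_minutes + profile.prep_minutes) * profile.exam_count
    return load / profile.rated_minutes


def _minutes(delta: pd.Timedelta) -> float:
    return delta.total_seconds() / 60.0


def mean_wait(records: Sequence[ExamRecord]) -> float:
    """X21: mean minutes from appointment slot to exam start.

    Only records carrying a ``scheduled_time`` count (the appointment count
    may be smaller than the exam count); an exam that started early
    contributes a zero wait rather than a negative one.
    """
    waits = [
        max(0.0, _minutes(r.exam_start - r.scheduled_time))
        for r in records
        if r.scheduled_time is not None
    ]
    if not waits:
        raise ValidationError("no appointment records: mean wait undefined")
    return float(np.mean(waits))


def mean_interval(records: Sequence[ExamRecord]) -> float:
    """X22: mean idle minutes between consecutive exams on one device.

    Records are ordered by exam start internally; overlapping exams
    contribute a zero gap.
    """
    if len(records) < 2:
        raise ValidationError("need at least two exams to compute intervals")
    ordered = sorted(records, key=lambda r: r.exam_start)
    gaps = [
        max(0.0, _minutes(b.exam_start - a.exam_end))
        for a, b in zip(ordered, ordered[1:])
    ]
    return float(np.mean(gaps))


def life_index(profile: EquipmentProfile) -> float:
    """X31: age over expected useful life (may exceed 1 for old devices)."""
    return profile.age_years / profile.expected_life_years


def failure_count(profile: EquipmentProfile) -> int:
    """X32: total breakdowns recorded over the period."""
    return int(profile.failure_count)


def cost_benefit_ratio(profile: EquipmentProfile) -> float:
    """X41: period revenue over period operating cost."""
    if profile.operating_cost <= 0:
        raise ValidationError(
            f"{profile.equipment_id}: operating_cost must be positive"
        )
    return profile.total_revenue / profile.operating_cost


def payback_period(profile: EquipmentProfile) -> float:
    """X42: purchase price over net period profit, in periods.

    A device whose revenue does not cover its operating cost never pays
    back; ``inf`` is returned (and replaced by a cohort-level sentinel in
    :func:`build_decision_matrix`).  Revenue exactly equal to cost leaves
    the ratio undefined.
    """
    net = profile.total_revenue - profile.operating_cost
    if net == 0:
        raise ValidationError(
            f"{profile.equipment_id}: revenue equals operating cost, "
            "undefined payback"
        )
    if net < 0:
        return math.inf
    return profile.purchase_price / net


def indicator_vector(
    profile: EquipmentProfile,
    records: Sequence[ExamRecord] | None = None,
) -> dict[str, float]:
    """All nine indicators for one device; X21/X22 require exam records."""
    vec = {
        "X11": operating_saturation(profile),
        "X12": equipment_utilization(profile),
        "X13": work_intensity(profile),
        "X31": life_index(profile),
        "X32": float(failure_count(profile)),
        "X41": cost_benefit_ratio(profile),
        "X42": payback_period(profile),
    }
    if records is None:
        raise ValidationError(
            f"{profile.equipment_id}: exam records required for X21/X22"
        )
    vec["X21"] = mean_wait(records)
    vec["X22"] = mean_interval(records)
    return {k: vec[k] for k in INDICATOR_IDS}


def build_decision_matrix(
    profiles: Sequence[EquipmentProfile],
    records: Iterable[ExamRecord] | Mapping[str, Sequence[ExamRecord]],
    sentinel_factor: float = 10.0,
) -> DecisionMatrix:
    """Assemble the m x 9 decision matrix for a cohort of devices.

    ``records`` may be a flat iterable (grouped by ``equipment_id``
    internally) or a pre-grouped mapping.  Devices that never pay back
    (revenue below operating cost) receive a finite payback sentinel:
    ``sentinel_factor`` times the largest finite payback in the cohort,
    keeping the cost-direction ordering monotone.
    """
    if isinstance(records, Mapping):
        grouped: dict[str, list[ExamRecord]] = {
            k: list(v) for k, v in records.items()
        }
    else:
        grouped = {}
        for r in records:
            grouped.setdefault(r.equipment_id, []).append(r)

    ids = [p.equipment_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate equipment ids in profiles: {ids}")
    unknown = set(grouped) - set(ids)
    if unknown:
        raise ValidationError(
            f"exam records reference unknown equipment: {sorted(unknown)}"
        )

    rows = {}
    for p in profiles:
        rows[p.equipment_id] = indicator_vector(p, grouped.get(p.equipment_id))

    df = pd.DataFrame.from_dict(rows, orient="index").loc[ids, list(INDICATOR_IDS)]

    payback = df["X42"].to_numpy()
    if np.isinf(payback).any():
        finite = payback[np.isfinite(payback)]
        if finite.size == 0:
            raise ValidationError(
                "no device in the cohort has a finite payback; "
                "cannot form the payback sentinel"
            )
        sentinel = float(finite.max()) * sentinel_factor
        flagged = [i for i, v in zip(ids, payback) if math.isinf(v)]
        warnings.warn(
            f"devices {flagged} never pay back; payback set to sentinel "
            f"{sentinel:g} (= {sentinel_factor:g} x cohort max)",
            stacklevel=2,
        )
        df["X42"] = np.where(np.isinf(payback), sentinel, payback)

    defs = [IndicatorDefinition.default(c) for c in df.columns]
    return DecisionMatrix(values=df, indicator_defs=defs)
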