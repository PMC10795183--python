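"""Domain types and file interchange for equipment replacement prioritization.

The package evaluates *replacement priority* of large medical equipment
(the motivating case is a fleet of MRI scanners) on a nine-indicator
system spanning four aspects:

====================  ===========================================  =========
indicator             meaning                                      direction
====================  ===========================================  =========
X11 work saturation   exam workload relative to powered-on time    benefit
X12 utilization       working time / powered-on time               benefit
X13 work intensity    exam workload relative to rated time         benefit
X21 mean wait         mean patient wait (exam start - appointment) benefit
X22 mean interval     mean gap between consecutive exams           benefit
X31 life index        age / expected useful life                   benefit
X32 failure count     number of recorded breakdowns                benefit
X41 cost-benefit      revenue / operating cost                     cost
X42 payback period    purchase price / (revenue - operating cost)  cost
====================  ===========================================  =========

"benefit" columns support earlier replacement when large; "cost" columns
when small (a long payback argues for *delaying* replacement).

All interchange is plain text: CSV for matrices/panels/logs, JSON for
weight vectors and rankings.  Durations are minutes, timestamps ISO-8601,
currency an opaque non-negative real.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_IDS",
    "DEFAULT_DIRECTIONS",
    "BENEFIT",
    "COST",
    "ExamRecord",
    "EquipmentProfile",
    "IndicatorDefinition",
    "DecisionMatrix",
    "ExpertScorePanel",
    "WeightVector",
    "RankingResult",
    "read_decision_matrix",
    "read_expert_panel",
    "read_profiles",
    "read_exam_records",
    "write_decision_matrix",
    "write_weight_vector",
    "read_weight_vector",
    "write_ranking",
    "read_ranking",
]

BENEFIT = "benefit"
COST = "cost"

INDICATOR_IDS: tuple[str, ...] = (
    "X11", "X12", "X13", "X21", "X22", "X31", "X32", "X41", "X42",
)

#: Default criterion directions: every operational/social/technical
#: indicator is a benefit criterion, the two economic ones are costs.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "X11": BENEFIT, "X12": BENEFIT, "X13": BENEFIT,
    "X21": BENEFIT, "X22": BENEFIT,
    "X31": BENEFIT, "X32": BENEFIT,
    "X41": COST, "X42": COST,
}

INDICATOR_NAMES: dict[str, str] = {
    "X11": "work saturation",
    "X12": "equipment utilization",
    "X13": "work intensity",
    "X21": "average patient waiting time",
    "X22": "average inter-exam interval",
    "X31": "life index",
    "X32": "failure count",
    "X41": "cost-benefit ratio",
    "X42": "payback period",
}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


@dataclass(frozen=True)
class ExamRecord:
    """One examination on one piece of equipment.

    ``scheduled_time`` is the appointment slot and may be absent (walk-in);
    waiting time is only defined for records that have one.
    """

    equipment_id: str
    exam_start: pd.Timestamp
    exam_end: pd.Timestamp
    scheduled_time: pd.Timestamp | None = None
    revenue: float = 0.0

    def __post_init__(self) -> None:
        if self.exam_end < self.exam_start:
            raise ValidationError(
                f"exam_end before exam_start for {self.equipment_id!r} "
                f"({self.exam_start} .. {self.exam_end})"
            )
        if self.revenue < 0:
            raise ValidationError(f"negative revenue for {self.equipment_id!r}")


@dataclass
class EquipmentProfile:
    """Period-level operational and financial summary of one device.

    Durations are minutes over the observation period; ``rated_minutes``
    defaults to an 8-hour working day times the number of days observed.
    """

    equipment_id: str
    model_name: str = ""
    purchase_price: float = 0.0          # C_v
    operating_cost: float = 0.0          # C_t, per period
    total_revenue: float = 0.0           # R_t, per period
    age_years: float = 0.0
    expected_life_years: float = 6.0     # reference useful life
    power_on_minutes: float = 0.0
    working_minutes: float = 0.0
    rated_minutes: float = 0.0
    failure_count: int = 0
    mean_exam_minutes: float = 0.0       # tau, mean exam duration
    exam_count: int = 0                  # completed exams in the period
    prep_minutes: float = 2.0            # per-exam preparation allowance

    def __post_init__(self) -> None:
        if self.expected_life_years <= 0:
            raise ValidationError(
                f"{self.equipment_id}: expected_life_years must be positive"
            )
        for name in ("power_on_minutes", "working_minutes", "rated_minutes",
                     "mean_exam_minutes", "prep_minutes", "age_years"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.equipment_id}: {name} negative")
        if self.working_minutes > self.power_on_minutes:
            raise ValidationError(
                f"{self.equipment_id}: working_minutes "
                f"({self.working_minutes}) exceeds power_on_minutes "
                f"({self.power_on_minutes})"
            )
        if self.failure_count < 0:
            raise ValidationError(f"{self.equipment_id}: failure_count negative")


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    name: str = ""
    direction: str = BENEFIT

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise ValidationError(
                f"direction must be {BENEFIT!r} or {COST!r}, "
                f"got {self.direction!r}"
            )

    @classmethod
    def default(cls, indicator_id: str) -> "IndicatorDefinition":
        return cls(
            indicator_id=indicator_id,
            name=INDICATOR_NAMES.get(indicator_id, indicator_id),
            direction=DEFAULT_DIRECTIONS.get(indicator_id, BENEFIT),
        )


@dataclass
class DecisionMatrix:
    """Equipment x indicator matrix with per-column criterion directions."""

    values: pd.DataFrame                       # index: equipment, cols: indicators
    indicator_defs: list[IndicatorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.indicator_defs:
            self.indicator_defs = [
                IndicatorDefinition.default(c) for c in self.values.columns
            ]
        cols = list(self.values.columns)
        def_ids = [d.indicator_id for d in self.indicator_defs]
        if cols != def_ids:
            raise ValidationError(
                f"indicator definitions {def_ids} do not match columns {cols}"
            )
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValidationError(
                f"decision matrix must be at least 2x2, got {self.values.shape}"
            )
        if self.values.isna().any().any():
            r, c = next(
                (r, c)
                for r in self.values.index
                for c in self.values.columns
                if pd.isna(self.values.at[r, c])
            )
            raise ValidationError(f"missing value at ({r}, {c})")

    @property
    def equipment_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def directions(self) -> dict[str, str]:
        return {d.indicator_id: d.direction for d in self.indicator_defs}

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpertScorePanel:
    """Experts x indicators importance scores on a 0-10 scale."""

    scores: pd.DataFrame                        # index: experts, cols: indicators

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValidationError("expert panel contains missing scores")
        arr = self.scores.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValidationError("expert panel is empty")
        if (arr < 0).any() or (arr > 10).any():
            bad = np.argwhere((arr < 0) | (arr > 10))[0]
            raise ValidationError(
                f"score {arr[tuple(bad)]} outside [0, 10] at expert "
                f"{self.scores.index[bad[0]]!r}, indicator "
                f"{self.scores.columns[bad[1]]!r}"
            )

    @property
    def expert_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_experts(self) -> int:
        return self.scores.shape[0]


@dataclass
class WeightVector:
    """Non-negative indicator weights summing to one."""

    indicator_ids: list[str]
    weights: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.indicator_ids) != self.weights.shape[0]:
            raise ValidationError("weights/indicator_ids length mismatch")
        if (self.weights < -1e-12).any():
            raise ValidationError(f"negative weight in {self.method_tag!r}")
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"weights sum to {self.weights.sum()!r}, expected 1"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.indicator_ids)

    def aligned_to(self, indicator_ids: Sequence[str]) -> np.ndarray:
        """Weights reordered to ``indicator_ids``; errors on mismatch."""
        if set(indicator_ids) != set(self.indicator_ids):
            raise ValidationError(
                f"weight vector covers {self.indicator_ids}, "
                f"matrix needs {list(indicator_ids)}"
            )
        s = self.as_series()
        return s.loc[list(indicator_ids)].to_numpy()


@dataclass
class RankingResult:
    """Per-equipment scores and ranks for one ranking method.

    Rank 1 is the highest replacement priority; ties get average ranks.
    ``diagnostics`` carries method-specific intermediates (distances, gray
    relational degrees, S/R/Q ...), keyed by name, each a per-equipment
    sequence.
    """

    equipment_ids: list[str]
    method_tag: str
    scores: np.ndarray
    ranks: np.ndarray
    diagnostics: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        m = len(self.equipment_ids)
        if self.scores.shape != (m,) or self.ranks.shape != (m,):
            raise ValidationError("scores/ranks shape mismatch")
        if not math.isclose(float(self.ranks.sum()), m * (m + 1) / 2):
            raise ValidationError("ranks are not a (tie-averaged) permutation")

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"score": self.scores, "rank": self.ranks},
            index=pd.Index(self.equipment_ids, name="equipment_id"),
        )
        for key, vals in self.diagnostics.items():
            df[key] = vals
        return df


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_decision_matrix(
    path: str | Path,
    direction_map: Mapping[str, str] | None = None,
) -> DecisionMatrix:
    """Read an equipment x indicator CSV (first column = equipment id).

    Column directions default to the standard nine-indicator system;
    unknown indicator columns must be given a direction via
    ``direction_map`` (values ``"benefit"``/``"cost"``).
    """
    df = _read_csv(path)
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        c = df.columns[df.isna().any(axis=0)][0]
        raise ValidationError(f"missing value at ({r}, {c})")
    direction_map = dict(direction_map or {})
    defs = []
    for col in df.columns:
        if col in direction_map:
            defs.append(IndicatorDefinition(col, INDICATOR_NAMES.get(col, col),
                                            direction_map[col]))
        elif col in DEFAULT_DIRECTIONS:
            defs.append(IndicatorDefinition.default(col))
        else:
            raise ValidationError(
                f"unknown indicator {col!r} has no direction; "
                f"pass direction_map={{{col!r}: 'benefit'|'cost'}}"
            )
    return DecisionMatrix(values=df.astype(float), indicator_defs=defs)


def write_decision_matrix(matrix: DecisionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, index_label="equipment_id")


def read_expert_panel(path: str | Path) -> ExpertScorePanel:
    """Read an experts x indicators CSV of 0-10 importance scores."""
    df = _read_csv(path)
    if df.isna().any().any():
        raise ValidationError(f"missing score in expert panel {path}")
    return ExpertScorePanel(scores=df.astype(float))


def write_expert_panel(panel: ExpertScorePanel, path: str | Path) -> None:
    panel.scores.to_csv(path, index_label="expert_id")


def read_profiles(path: str | Path) -> list[EquipmentProfile]:
    """Read one EquipmentProfile per CSV row (column names = field names)."""
    df = pd.read_csv(path)
    if "equipment_id" not in df.columns:
        raise ValidationError("profile CSV needs an equipment_id column")
    profiles = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if not pd.isna(row[k])}
        kwargs["equipment_id"] = str(kwargs["equipment_id"])
        if "failure_count" in kwargs:
            kwargs["failure_count"] = int(kwargs["failure_count"])
        if "exam_count" in kwargs:
            kwargs["exam_count"] = int(kwargs["exam_count"])
        profiles.append(EquipmentProfile(**kwargs))
    return profiles


def write_profiles(profiles: Iterable[EquipmentProfile], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in profiles]).to_csv(path, index=False)


def read_exam_records(path: str | Path) -> list[ExamRecord]:
    """Read exam logs: equipment_id, scheduled_time, exam_start, exam_end, revenue."""
    df = pd.read_csv(path)
    needed = {"equipment_id", "exam_start", "exam_end"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"exam CSV needs columns {sorted(needed)}")
    records = []
    for i, row in df.iterrows():
        if pd.isna(row["exam_start"]) or pd.isna(row["exam_end"]):
            raise ValidationError(f"missing exam time in row {i}")
        sched = row.get("scheduled_time")
        records.append(
            ExamRecord(
                equipment_id=str(row["equipment_id"]),
                exam_start=pd.Timestamp(row["exam_start"]),
                exam_end=pd.Timestamp(row["exam_end"]),
                scheduled_time=None if pd.isna(sched) else pd.Timestamp(sched),
                revenue=float(row.get("revenue", 0.0) or 0.0),
            )
        )
    return records


def write_exam_records(records: Iterable[ExamRecord], path: str | Path) -> None:
    rows = [
        {
            "equipment_id": r.equipment_id,
            "scheduled_time": "" if r.scheduled_time is None
            else r.scheduled_time.isoformat(),
            "exam_start": r.exam_start.isoformat(),
            "exam_end": r.exam_end.isoformat(),
            "revenue": r.revenue,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weight_vector(wv: WeightVector, path: str | Path,
                        extra: Mapping | None = None) -> None:
    """Serialize a weight vector as JSON at full float precision."""
    payload = {
        "method": wv.method_tag,
        "indicator_ids": list(wv.indicator_ids),
        "weights": [float(w) for w in wv.weights],
    }
    if extra:
        payload["meta"] = dict(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_weight_vector(path: str | Path) -> WeightVector:
    payload = json.loads(Path(path).read_text())
    return WeightVector(
        indicator_ids=list(payload["indicator_ids"]),
        weights=np.array(payload["weights"], dtype=float),
        method_tag=payload.get("method", ""),
    )


def write_ranking(result: RankingResult, path: str | Path,
                  extra: Mapping | None = None) -> None:
    payload = {
        "method": result.method_tag,
        "equipment_ids": list(result.equipment_ids),
        "scores": [float(s) for s in result.scores],
        "ranks": [float(r) for r in result.ranks],
        "diagnostics": {k: [float(x) for x in v]
                        for k, v in result.diagnostics.items()},
    }
    if extra:
        payload["meta"] = dict(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ranking(path: str | Path) -> RankingResult:
    payload = json.loads(Path(path).read_text())
    return RankingResult(
        equipment_ids=list(payload["equipment_ids"]),
        method_tag=payload.get("method", ""),
        scores=np.array(payload["scores"], dtype=float),
        ranks=np.array(payload["ranks"], dtype=float),
        diagnostics={k: list(v)
                     for k, v in payload.get("diagnostics", {}).items()},
    )
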