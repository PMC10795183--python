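"""Synthetic cohorts, expert panels, and the published MRI case-study
tables.

No raw fleet logs are publicly available for this class of problem, so
testing runs on two sources:

1. a *generator* that inverts the indicator definitions — given target
   values for the nine indicators it fabricates a period profile and an
   exam log that reproduce them (exactly when noise is off, in
   expectation otherwise);
2. *embedded reference tables* from the published four-scanner MRI case
   study (PCA loadings and weights, normalized fusion measures, method
   scores and ranks, and the expert worked example), used as mid-pipeline
   fixtures.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    EquipmentProfile,
    ExamRecord,
    ExpertScorePanel,
    INDICATOR_IDS,
    ValidationError,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_expert_panel",
    "MriCaseStudy",
    "mri_case_study",
    "default_cohort_spec",
]


@dataclass
class CohortSpec:
    """Target indicator values and noise levels for a synthetic fleet.

    ``targets`` maps equipment id to a full set of nine indicator targets.
    ``days`` sets the observation period (rated time is 8 h/day).
    Noise standard deviations are in minutes; zero noise makes the log
    reproduce the timing targets exactly.
    """

    targets: Mapping[str, Mapping[str, float]]
    days: int = 90
    base_exam_minutes: float = 28.0       # nominal exam duration used to size N
    prep_minutes: float = 2.0
    expected_life_years: float = 6.0
    operating_cost: float = 1.0e6         # per period, currency units
    duration_noise_sd: float = 0.0
    wait_noise_sd: float = 0.0
    gap_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for eq, t in self.targets.items():
            missing = set(INDICATOR_IDS) - set(t)
            if missing:
                raise ValidationError(
                    f"{eq}: missing indicator targets {sorted(missing)}"
                )
            if not 0 <= t["X12"] <= 1:
                raise ValidationError(f"{eq}: X12 target must lie in [0, 1]")
            if t["X32"] < 0 or t["X32"] != int(t["X32"]):
                raise ValidationError(f"{eq}: X32 must be a non-negative integer")
            for key in ("X11", "X13"):
                if t[key] <= 0:
                    raise ValidationError(f"{eq}: {key} target must be positive")
            for key in ("X21", "X22", "X31", "X42"):
                if t[key] < 0:
                    raise ValidationError(f"{eq}: {key} target must be >= 0")
            if t["X41"] <= 1:
                raise ValidationError(
                    f"{eq}: X41 must exceed 1 (device must run at a profit "
                    "for the payback target to be attainable)"
                )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    draw = rng.normal(mean, sd, size)
    return np.clip(draw, lower, None)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EquipmentProfile], list[ExamRecord], pd.DataFrame]:
    """Fabricate profiles, an exam log, and a failure log hitting the
    spec's indicator targets.

    The inversion: the exam count N is sized from the work-intensity
    target at the nominal exam duration, then the mean duration tau is
    solved so X13 is hit exactly; powered-on time follows from X11,
    working time from X12, age from X31, and the financials from X41/X42.
    Exams are laid out as one chronological stream with inter-exam gaps at
    the X22 target and appointment leads at the X21 target (plus noise).
    """
    rng = np.random.default_rng(spec.seed)
    eta_r = 480.0 * spec.days
    profiles: list[EquipmentProfile] = []
    records: list[ExamRecord] = []
    failure_rows = []

    for eq, t in spec.targets.items():
        n_exams = max(2, round(t["X13"] * eta_r
                               / (spec.base_exam_minutes + spec.prep_minutes)))
        tau = t["X13"] * eta_r / n_exams - spec.prep_minutes
        if tau <= 0:
            raise ValidationError(
                f"{eq}: X13 target {t['X13']} infeasible — implied mean exam "
                "duration is not positive"
            )
        eta_b = (tau + spec.prep_minutes) * n_exams / t["X11"]
        eta_w = t["X12"] * eta_b

        r_t = t["X41"] * spec.operating_cost
        c_v = t["X42"] * (r_t - spec.operating_cost)

        profile = EquipmentProfile(
            equipment_id=eq,
            model_name=eq,
            purchase_price=c_v,
            operating_cost=spec.operating_cost,
            total_revenue=r_t,
            age_years=t["X31"] * spec.expected_life_years,
            expected_life_years=spec.expected_life_years,
            power_on_minutes=eta_b,
            working_minutes=eta_w,
            rated_minutes=eta_r,
            failure_count=int(t["X32"]),
            mean_exam_minutes=tau,
            exam_count=n_exams,
            prep_minutes=spec.prep_minutes,
        )
        profiles.append(profile)

        durations = _truncated_normal(rng, tau, spec.duration_noise_sd,
                                      n_exams, lower=1.0)
        gaps = _truncated_normal(rng, t["X22"], spec.gap_noise_sd, n_exams - 1)
        waits = _truncated_normal(rng, t["X21"], spec.wait_noise_sd, n_exams)
        revenue_per_exam = r_t / n_exams

        start = pd.Timestamp("2023-01-02 08:00:00")
        for i in range(n_exams):
            end = start + pd.Timedelta(minutes=float(durations[i]))
            records.append(
                ExamRecord(
                    equipment_id=eq,
                    scheduled_time=start - pd.Timedelta(minutes=float(waits[i])),
                    exam_start=start,
                    exam_end=end,
                    revenue=revenue_per_exam,
                )
            )
            if i < n_exams - 1:
                start = end + pd.Timedelta(minutes=float(gaps[i]))

        span_minutes = spec.days * 24 * 60
        for minute in sorted(rng.uniform(0, span_minutes, int(t["X32"]))):
            failure_rows.append(
                {
                    "equipment_id": eq,
                    "failure_time": (
                        pd.Timestamp("2023-01-02")
                        + pd.Timedelta(minutes=float(minute))
                    ).isoformat(),
                }
            )

    failures = pd.DataFrame(failure_rows,
                            columns=["equipment_id", "failure_time"])
    return profiles, records, failures


def generate_expert_panel(
    n_experts: int = 8,
    anchors: Mapping[str, float] | Sequence[float] | None = None,
    consensus: float = 0.8,
    seed: int = 0,
    dispersion: float = 2.0,
    indicator_ids: Sequence[str] = INDICATOR_IDS,
) -> ExpertScorePanel:
    """Synthesize an experts x indicators importance panel.

    Scores are drawn around per-indicator anchor values with spread
    ``dispersion * (1 - consensus)``; at ``consensus=1`` every expert
    returns the anchor exactly.  Scores are clipped to the 0-10 scale.
    """
    if n_experts < 1:
        raise ValidationError("need at least one expert")
    if not 0 <= consensus <= 1:
        raise ValidationError("consensus must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if anchors is None:
        anchors = {k: a for k, a in zip(
            indicator_ids, rng.uniform(4, 9, len(indicator_ids)))}
    elif not isinstance(anchors, Mapping):
        anchors = dict(zip(indicator_ids, anchors))
    mu = np.array([anchors[k] for k in indicator_ids], dtype=float)
    sd = dispersion * (1.0 - consensus)
    scores = mu + (rng.normal(0.0, sd, (n_experts, len(mu))) if sd > 0
                   else np.zeros((n_experts, len(mu))))
    df = pd.DataFrame(
        np.clip(scores, 0.0, 10.0),
        index=[f"expert_{i+1}" for i in range(n_experts)],
        columns=list(indicator_ids),
    )
    return ExpertScorePanel(scores=df)


# ---------------------------------------------------------------------------
# published MRI case-study tables
# ---------------------------------------------------------------------------

_SCANNERS = ("Signa HDx", "MR750", "MR750W", "Prisma")


@dataclass
class MriCaseStudy:
    """Reference values from the published four-scanner MRI case study."""

    #: PCA component loadings (9 indicators x 4 retained components).
    pca_loadings: pd.DataFrame
    #: Eigenvalues of the four retained components.
    pca_eigenvalues: np.ndarray
    #: Variance shares of the retained components (fractions).
    pca_variance_shares: np.ndarray
    #: Printed composite scores and normalized weights per indicator.
    pca_scores: pd.Series
    pca_weights: pd.Series
    #: Normalized fusion measures per scanner: D+, D-, L+, L-.
    fusion_measures: pd.DataFrame
    #: Method scores per scanner (GRA, TOPSIS, GRA-TOPSIS, VIKOR).
    method_scores: pd.DataFrame
    #: Printed replacement ranks per method.
    method_ranks: pd.DataFrame
    #: Expert worked example: descending-sorted importance scores for the
    #: work-saturation indicator, and the printed contribution vector.
    expert_sorted_scores: np.ndarray
    expert_contributions: np.ndarray
    #: Concordance summary over GRA / TOPSIS / GRA-TOPSIS.
    concordance_rank_averages: pd.Series
    concordance_medians: pd.Series
    kendall_w: float
    kendall_chi2: float
    kendall_p: float


def mri_case_study() -> MriCaseStudy:
    """Embedded reference tables of the four-scanner MRI case study."""
    loadings = pd.DataFrame(
        [
            [0.443, 0.158, 0.297, 0.218],
            [0.402, 0.246, 0.325, 0.321],
            [0.392, 0.195, 0.123, 0.335],
            [0.226, 0.576, 0.062, 0.057],
            [0.358, 0.151, 0.229, 0.348],
            [0.388, 0.151, 0.367, 0.397],
            [0.097, 0.612, 0.336, 0.046],
            [0.381, 0.099, 0.432, 0.328],
            [0.065, 0.339, 0.549, 0.588],
        ],
        index=list(INDICATOR_IDS),
        columns=["PC1", "PC2", "PC3", "PC4"],
    )
    scores = pd.Series(
        [0.333, 0.347, 0.302, 0.255, 0.293, 0.335, 0.237, 0.322, 0.259],
        index=list(INDICATOR_IDS),
    )
    weights = pd.Series(
        [0.124, 0.129, 0.113, 0.095, 0.109, 0.125, 0.088, 0.120, 0.096],
        index=list(INDICATOR_IDS),
    )
    fusion = pd.DataFrame(
        [
            [1.000, 0.646, 0.873, 1.000],
            [0.622, 0.985, 0.979, 0.875],
            [0.410, 1.000, 1.000, 0.818],
            [0.570, 0.959, 0.982, 0.859],
        ],
        index=list(_SCANNERS),
        columns=["D_pos", "D_neg", "L_pos", "L_neg"],
    )
    method_scores = pd.DataFrame(
        {
            "GRA": [0.864, 0.756, 0.707, 0.742],
            "TOPSIS": [0.613, 0.393, 0.296, 0.379],
            "GRA-TOPSIS": [0.568, 0.433, 0.380, 0.424],
            "VIKOR": [0.000, 0.831, 0.807, 0.990],
        },
        index=list(_SCANNERS),
    )
    method_ranks = pd.DataFrame(
        {
            "GRA": [1, 3, 4, 2],
            "TOPSIS": [1, 2, 4, 3],
            "GRA-TOPSIS": [1, 2, 4, 3],
            "VIKOR": [1, 3, 2, 4],
        },
        index=list(_SCANNERS),
    )
    return MriCaseStudy(
        pca_loadings=loadings,
        pca_eigenvalues=np.array([4.013, 1.652, 1.186, 0.924]),
        pca_variance_shares=np.array([0.4459, 0.1836, 0.1318, 0.1027]),
        pca_scores=scores,
        pca_weights=weights,
        fusion_measures=fusion,
        method_scores=method_scores,
        method_ranks=method_ranks,
        expert_sorted_scores=np.array([9, 8, 8, 8, 8, 7, 7, 6], dtype=float),
        expert_contributions=np.array(
            [0.07, 0.44, 1.31, 2.19, 2.19, 1.15, 0.38, 0.05]
        ),
        concordance_rank_averages=pd.Series(
            [3.0, 1.25, 1.75], index=["GRA", "TOPSIS", "GRA-TOPSIS"]
        ),
        concordance_medians=pd.Series(
            [0.749, 0.386, 0.428], index=["GRA", "TOPSIS", "GRA-TOPSIS"]
        ),
        kendall_w=0.812,
        kendall_chi2=6.5,
        kendall_p=0.039,
    )


def default_cohort_spec(seed: int = 0, noisy: bool = False) -> CohortSpec:
    """A realistic four-scanner fleet over a 90-day observation period.

    Targets emulate a mixed-age MRI fleet: one device past its useful life
    and heavily loaded, one new and lightly loaded, two in between.  Noise
    levels (when on) reflect minute-scale scatter in exam durations,
    appointment leads, and turnaround gaps.
    """
    targets = {
        "MRI-A": {"X11": 0.85, "X12": 0.90, "X13": 1.00, "X21": 25.0,
                  "X22": 6.0, "X31": 1.50, "X32": 6, "X41": 1.8, "X42": 4.5},
        "MRI-B": {"X11": 0.70, "X12": 0.80, "X13": 0.85, "X21": 18.0,
                  "X22": 8.0, "X31": 1.00, "X32": 3, "X41": 2.2, "X42": 3.0},
        "MRI-C": {"X11": 0.55, "X12": 0.70, "X13": 0.60, "X21": 12.0,
                  "X22": 12.0, "X31": 0.40, "X32": 1, "X41": 2.6, "X42": 2.2},
        "MRI-D": {"X11": 0.65, "X12": 0.75, "X13": 0.75, "X21": 15.0,
                  "X22": 10.0, "X31": 0.70, "X32": 2, "X41": 2.4, "X42": 2.8},
    }
    return CohortSpec(
        targets=targets,
        days=90,
        duration_noise_sd=4.0 if noisy else 0.0,
        wait_noise_sd=5.0 if noisy else 0.0,
        gap_noise_sd=2.0 if noisy else 0.0,
        seed=seed,
    )
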