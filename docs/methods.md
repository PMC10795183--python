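# Methods

This note records the model, the numerical choices, and the places where
the published construction was ambiguous and the package had to commit to
a reading.

## Indicator system

Nine indicators over four aspects (operational security, social benefit,
technical state, economics) are computed per device over an observation
period. Durations are minutes throughout; timestamps are ISO-8601;
currency is an opaque non-negative real.

| id | definition | units | direction |
|----|------------|-------|-----------|
| X11 | (τ + prep)·N / η_b | — | benefit |
| X12 | η_w / η_b | fraction | benefit |
| X13 | (τ + prep)·N / η_r | — | benefit |
| X21 | mean(exam_start − scheduled), clamped ≥ 0 per record | min | benefit |
| X22 | mean(start_i − end_{i−1}), clamped ≥ 0 per gap | min | benefit |
| X31 | age / expected life (default 6 y) | — | benefit |
| X32 | Σ failures | count | benefit |
| X41 | R_t / C_t | — | cost |
| X42 | C_v / (R_t − C_t) | periods | cost |

Committed readings of ambiguous definitions:

- **Workload parenthesization.** The saturation/intensity formula is read
  as (τ + 2)·N / η — the "+2" is a per-exam preparation allowance added
  to the mean exam duration τ, configurable via `prep_minutes`.
- **Waiting time.** X21 is exam start minus the appointment slot. A
  literal subtraction of exam end from exam start would measure exam
  duration, not waiting; each record's wait is clamped at zero (early
  starts do not earn negative waits). The denominator counts only records
  that carry an appointment time, which may be fewer than the exam count;
  both counts are exposed separately.
- **Interval.** X22 is the mean over the m−1 consecutive gaps (records
  sorted by start time internally); overlapping exams contribute zero.
- **Non-recoverable payback.** If R_t < C_t the device never pays back.
  The per-device function returns +inf; at cohort level the value is
  replaced by `sentinel_factor` (default 10) times the largest finite
  payback in the cohort, which keeps the cost-direction ordering monotone
  ("longer payback → delay replacement") without breaking min-max
  normalization. R_t = C_t is an error. If no device in a cohort has a
  finite payback the sentinel is undefined and the build errors.

## Direction semantics

All normalization is direction-aware min-max: benefit columns map their
largest raw value to 1, cost columns their smallest. After adjustment,
1 always means "performs best on this criterion", so the positive ideal
is the best-performing synthetic profile and the negative ideal the
worst. Replacement priority is then *similarity to the negative ideal*:
the fusion orientation, plain-GRA reference row, TOPSIS closeness and the
VIKOR utility scale all encode "replace the device that performs worst
under the stated directions". One consequence worth stating plainly:
with every operational/technical indicator a benefit criterion, the model
prioritizes replacing underutilized and economically weak devices, not
overworked ones. A constant column is normalized to 0.5 with a warning
(it carries no ordering information).

## COWA expert weighting

Experts score each indicator 0–10. Scores are accepted as reals. The
position weights θ_{j+1} = C(n−1, j)/2^{n−1} are symmetric and sum to 1;
applied to the descending-sorted scores they form a convex combination
whose extreme positions get weight 2^{1−n} — a deliberate damping of
outlier experts. Equal scores make tie order irrelevant; a stable sort
keeps the exposed contribution vector reproducible. Per-indicator
aggregates are normalized across indicators to the weight vector; an
all-zero panel is an error.

## PCA objective weighting

The correlation matrix of the (min-max, direction-adjusted) normalized
indicators is eigendecomposed (`numpy.linalg.eigh`; a z-score
normalization is exposed as an alternative — the correlations, and hence
the weights, are identical, since Pearson correlation is affine-invariant).
Retention policies: cumulative explained variance ≥ 0.85 (default),
Kaiser (λ ≥ 1), or a fixed count. The default is cumulative because on
the reference case the fourth component (λ = 0.924) fails Kaiser yet is
retained in the published analysis (cumulative 86.4%).

Indicator scores are the variance-weighted average of absolute loadings
over the retained components, renormalized by the cumulative variance:
score_i = Σ_{j≤p} a_j|c_ij| / Σ_{j≤p} a_j, weight_i = score_i / Σ score.
Absolute values make the weights invariant to eigenvector sign flips.
Recomputing the reference table from its 3-dp printed loadings reproduces
all score/weight cells to within one unit in the third decimal (three
cells differ by exactly one printed ulp, an input-rounding artifact) and
the spot-checked cells exactly.

## Game-theoretic combination

The combined vector W* = Σ λ*_k W_k solves A λ = b with A_jk = W_j·W_k
and b_j = W_j·W_j — the standard first-order system of the
combination-weighting literature (a printed variant with
b = (W₁W₁ᵀ, W₁W₂ᵀ) does not follow from differentiating the deviation
objective and is not used). λ is normalized to sum to one; negative
coefficients beyond numerical noise are clipped and renormalized with a
warning so W* remains a convex combination and weight non-negativity
survives. Singular or ill-conditioned systems (identical/collinear
inputs, condition number > 1e12) fall back to the equal mix with a
warning. Note the deviation objective itself, restricted to the simplex,
is minimized by the trivial equal mix; the normal-equation solution
departs from it exactly when the input norms differ, which is what makes
the method informative. The solution never does worse than either pure
input on the objective (true of any convex mix), and this is verified in
tests.

## GRA-TOPSIS fusion

With S = w·z (weights times normalized matrix): d± are Euclidean
distances to the column-max/min profiles; gray relational coefficients
use h = (Δmin + ρΔmax)/(Δ + ρΔmax) with the extremes taken globally over
each Δ matrix and ρ = 0.5 by default (at Δmin = 0 the coefficients live
in [1/3, 1]); gray degrees are the weight-weighted row means (a uniform
mean is available via `gray_degree_weighting="uniform"`; the indicator
weights thus enter twice by default, matching the published
construction — a constant 1/n prefactor is dropped as it cancels in the
next step). Each of d+, d−, l+, l− is divided by its own maximum, giving
D±, L± with unit maxima.

The decision factor is ξ = T+/(T+ + T−). Two orientations are exposed:

- **priority** (default): T+ = α₁D+ + α₂L−, T− = α₁D− + α₂L+. This is
  the assignment that reproduces the published case-study scores exactly
  (0.568, 0.433, 0.380, 0.424); large ξ = replace sooner.
- **proximity**: the mirrored assignment (large ξ = performs best). The
  two are exact complements, ξ_pri + ξ_prox = 1, which is tested.

Degenerate inputs: identical rows make Δmax = 0 (coefficients set to 1
with a warning); T+ + T− = 0 is an error. Ranks are 1 = replace first,
ties averaged (`scipy.stats.rankdata`).

Comparators: plain GRA scores each device by the weighted gray degree to
the all-worst row of z; plain TOPSIS by d+/(d+ + d−) (closeness to the
negative ideal, so the worst performer scores highest); VIKOR runs on the
replacement-need scale u = 1 − z with standard S/R/Q, v = 0.5, ranked
ascending in Q (Q = 0 replaces first). Constant criteria contribute no
VIKOR regret; if all devices tie, all Q are 0 with a warning.

## Concordance

Kendall's W follows the "k related samples" convention: each device is a
block ranking the k method *scores*; W = 12S/(n²(k³−k)), χ² = n(k−1)W
with k−1 degrees of freedom. This orientation — not methods ranking
devices — is what reproduces the published concordance table (W = 0.812,
χ² = 6.5, p = 0.039 for the three-method comparison); the transpose is
exposed as an option (on the reference data it degenerates to W = 1
because all three methods order the scanners identically). Tie-averaged
ranks are used; the tie-correction term is off by default (no ties occur
in the reference data) and available via a flag. p-values are reported,
never used for automated decisions.

## Synthetic generator

`generate_cohort` inverts the indicator definitions: the exam count N is
sized from the X13 target at a nominal 28-minute exam (+2 min
preparation), τ is then solved so X13 is exact despite rounding of N,
η_b follows from X11, η_w from X12, age from X31, and the financials
from X41/X42 at an operating-cost scale of 1e6 per period with constant
per-exam revenue. The exam log is one chronological stream (day
boundaries are not simulated; only rated time η_r = 480·days depends on
the period length): gaps at the X22 target, appointment leads at the X21
target, truncated-normal noise (defaults 4/5/2 min SD for
durations/waits/gaps when enabled, zero otherwise). With zero noise every
indicator round-trips to 1e−9; with noise the timing indicators hold in
expectation. Generators are pure functions of (spec, seed).

What the generator does *not* emulate: day-boundary scheduling, seasonal
or weekday load patterns, heterogeneous per-exam revenue, correlated
failure processes, or any MRI duty-cycle physics. Passing tests therefore
show the pipeline's algebra is right on data with the indicators'
statistical structure, not that the indicator system captures real fleet
behavior.

The default test fleet is four scanners over 90 days with mixed ages and
loads; infeasible targets (X12 outside [0,1], fractional failure counts,
X41 ≤ 1 meaning the device runs at a loss, non-positive workload) are
rejected at spec construction with the violated constraint named.

## Problem sizes

The reference-table computations are 4×4 and 9×4 — milliseconds. The
synthetic fleets used in tests and examples are four devices over 90
days (roughly 10⁴ exam records per cohort), which keeps the full suite
under a minute while exercising every stage end to end.

## Known limitations

- The raw 4×9 indicator matrix behind the published case study was never
  released, so end-to-end reproduction from logs is impossible; embedded
  reference values start at the mid-pipeline tables (normalized fusion
  measures, PCA loadings), and the published plain-GRA/TOPSIS score
  columns are not exactly derivable from them (they appear to use
  pre-normalization distances); those comparators follow the standard
  definitions here.
- Expert panels arrive final: no Delphi round management.
- No fuzzy/interval extensions, no factor rotation, no multi-period
  dynamics; one observation period per decision.
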