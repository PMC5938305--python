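"""Timeline-followback (TLFB-G) preparation and the longitudinal design matrix.

Raw TLFB-G records are day-level net gambling losses (SEK) per participant,
reported retrospectively by either the gambler or their concerned significant
other (CSO).  The modeling unit is the participant-week: the average daily
loss over the days observed in that calendar week.  Aggregating to weekly
averages keeps a zero interpretable the same way at every timepoint — "no
gambling that week".

Time enters the model as a restricted cubic spline in week with three knots
at the 10th/50th/90th percentiles of the observed week variable, plus a
post-baseline dummy that allows an abrupt drop at treatment start.  Treatment
arms are constrained to share the baseline mean: arm enters only through
interactions with the post-baseline columns, which are identically zero at
week 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WEEK_MAP",
    "IngestReport",
    "TimeDesign",
    "ingest_daily",
    "aggregate_weekly",
    "default_week_map",
    "place_knots",
    "rcs_basis",
    "build_design",
    "DESIGN_COLUMNS",
]

#: Calendar anchors for the trial schedule, in weeks from treatment start:
#: a ~30-day baseline month maps to week 0, the 10 treatment weeks to 1-10
#: (a 12-week completion window is accommodated by calendar position), the
#: post-treatment assessment to week 12, and the 3-/6-month follow-ups to
#: weeks 25 and 38.
POST_WEEK = 12
M3_WEEK = 25
M6_WEEK = 38

DESIGN_COLUMNS = [
    "intercept",
    "post",
    "week_lin",
    "week_nl",
    "post:arm",
    "week_lin:arm",
    "week_nl:arm",
]


class TlfbError(ValueError):
    pass


@dataclass
class IngestReport:
    n_rows: int = 0
    n_clamped: int = 0
    clamped_keys: list = field(default_factory=list)


def ingest_daily(records, clamp_negative: bool = True):
    """Validate raw day-level loss rows and return (DataFrame, IngestReport).

    ``records`` is a DataFrame (or convertible) with columns participant_id,
    rater, study_day, net_loss.  Winning days (negative net loss) are clamped
    to zero when ``clamp_negative`` and each clamp is logged; duplicates on
    (participant_id, rater, study_day) are rejected.
    """
    df = pd.DataFrame(records).copy()
    required = ["participant_id", "rater", "study_day", "net_loss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TlfbError(f"missing columns: {missing}")

    loss = pd.to_numeric(df["net_loss"], errors="coerce")
    bad = loss.isna() & df["net_loss"].notna() | df["net_loss"].isna()
    if bad.any():
        rows = df.index[bad].tolist()
        raise TlfbError(f"non-numeric net_loss in rows {rows}")
    df["net_loss"] = loss.astype(float)
    df["study_day"] = df["study_day"].astype(int)

    key = ["participant_id", "rater", "study_day"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        pid, rater, day = df.loc[dup, key].iloc[0].tolist()
        raise TlfbError(
            f"duplicate daily record for key ({pid!r}, {rater!r}, {int(day)})"
        )

    report = IngestReport(n_rows=len(df))
    neg = df["net_loss"] < 0
    if neg.any():
        if not clamp_negative:
            raise TlfbError(
                f"{int(neg.sum())} negative net_loss rows and clamp_negative=False"
            )
        report.n_clamped = int(neg.sum())
        report.clamped_keys = [tuple(r) for r in df.loc[neg, key].itertuples(index=False)]
        df.loc[neg, "net_loss"] = 0.0
    return df.reset_index(drop=True), report


def default_week_map(study_days: Sequence[int]) -> Mapping[int, int]:
    """Map study days to analysis weeks.

    Negative days (the baseline month) map to week 0; day ``d >= 0`` maps to
    calendar week ``d // 7 + 1``, so treatment weeks are 1-10 (or up to 12
    with the completion window) and later assessment windows land on their
    calendar positions.
    """
    return {int(d): (0 if d < 0 else int(d) // 7 + 1) for d in np.unique(study_days)}


def aggregate_weekly(daily: pd.DataFrame, week_map: Optional[Mapping[int, int]] = None) -> pd.DataFrame:
    """Aggregate day-level losses to participant-week average daily losses.

    The weekly value is the arithmetic mean over the days *observed* in that
    week; weeks with no observed days are simply absent (missing at random).
    Returns columns participant_id, rater, week, avg_daily_loss,
    n_days_observed.
    """
    if week_map is None:
        week_map = default_week_map(daily["study_day"])
    df = daily.copy()
    df["week"] = df["study_day"].map(week_map)
    if df["week"].isna().any():
        days = sorted(df.loc[df["week"].isna(), "study_day"].unique().tolist())
        raise TlfbError(f"study days missing from week_map: {days}")
    out = (
        df.groupby(["participant_id", "rater", "week"], as_index=False)
        .agg(avg_daily_loss=("net_loss", "mean"), n_days_observed=("net_loss", "size"))
        .sort_values(["participant_id", "rater", "week"])
        .reset_index(drop=True)
    )
    out["week"] = out["week"].astype(int)
    return out


def place_knots(weeks: Sequence[float]) -> np.ndarray:
    """Knots at the 10th/50th/90th percentiles of the observation-level weeks.

    Percentiles use the linear-interpolation convention.  Raises if fewer
    than three distinct week values are present (the spline would be
    unidentifiable).
    """
    w = np.asarray(weeks, dtype=float)
    if np.unique(w).size < 3:
        raise TlfbError("need >= 3 distinct week values to place spline knots")
    knots = np.percentile(w, [10, 50, 90], method="linear")
    if not (knots[0] < knots[1] < knots[2]):
        raise TlfbError(f"degenerate knots {knots}; week distribution too concentrated")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis with three knots: columns (linear, nonlinear).

    The nonlinear column is the truncated-power construction constrained to
    be linear beyond both boundary knots, scaled by ``(k3 - k1)**2`` so both
    columns live on the scale of ``x``.
    """
    x = np.asarray(x, dtype=float)
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise TlfbError(f"knots must be strictly increasing, got {(k1, k2, k3)}")

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    nl = (
        cube(x - k1)
        - cube(x - k2) * (k3 - k1) / (k3 - k2)
        + cube(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, nl])


@dataclass
class TimeDesign:
    """Design matrix for the longitudinal models, with the baseline constraint.

    ``matrix`` has columns :data:`DESIGN_COLUMNS`; ``arm`` is 0/1 with the
    couples-therapy arm (BCT) as reference and the individual-CBT arm coded 1.
    Spline columns are centered at week 0, and arm enters only through
    interactions with post-baseline columns, so every arm-dependent column is
    identically zero at baseline.
    """

    matrix: pd.DataFrame
    knots: np.ndarray
    weeks: np.ndarray
    arm: np.ndarray
    participant_id: np.ndarray
    arm_x_spline: bool = True

    @property
    def X(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def columns(self):
        return list(self.matrix.columns)

    def row(self, week: float, arm) -> np.ndarray:
        """Covariate row for one (week, arm) cell; arm may be 0/1 or a label."""
        arm01 = _arm_code(arm)
        return _design_rows(np.array([week]), np.array([arm01]), self.knots, self.arm_x_spline)[0]


_ARM_CODES = {"bct": 0, "cbt": 1, 0: 0, 1: 1}


def _arm_code(a):
    key = a.lower() if isinstance(a, str) else a
    try:
        return _ARM_CODES[key]
    except (KeyError, TypeError):
        raise TlfbError(f"unknown arm label {a!r}; expected BCT or CBT") from None


def _design_rows(weeks, arm01, knots, arm_x_spline):
    basis = rcs_basis(weeks, knots)
    basis0 = rcs_basis(np.array([0.0]), knots)
    basis = basis - basis0  # both spline columns are 0 at week 0
    post = (weeks > 0).astype(float)
    cols = [np.ones_like(weeks, dtype=float), post, basis[:, 0], basis[:, 1]]
    a = arm01.astype(float)
    cols.append(post * a)
    if arm_x_spline:
        cols.append(basis[:, 0] * a)
        cols.append(basis[:, 1] * a)
    return np.column_stack(cols)


def build_design(
    weekly: pd.DataFrame,
    arms: Mapping,
    knots=None,
    arm_x_spline: bool = True,
) -> TimeDesign:
    """Build the :class:`TimeDesign` for a weekly loss table.

    ``arms`` maps participant_id to an arm label (BCT reference, CBT coded 1).
    With ``arm_x_spline`` the arm interacts with the post dummy and both
    spline columns; otherwise with the post dummy only.
    """
    weeks = weekly["week"].to_numpy(dtype=float)
    pid = weekly["participant_id"].to_numpy()
    unknown = sorted({p for p in pid if p not in arms})
    if unknown:
        raise TlfbError(f"participants without an arm label: {unknown}")
    arm01 = np.array([_arm_code(arms[p]) for p in pid])
    if knots is None:
        knots = place_knots(weeks)
    knots = np.asarray(knots, dtype=float)
    X = _design_rows(weeks, arm01, knots, arm_x_spline)
    cols = DESIGN_COLUMNS if arm_x_spline else DESIGN_COLUMNS[:5]
    matrix = pd.DataFrame(X, columns=cols)
    return TimeDesign(
        matrix=matrix,
        knots=knots,
        weeks=weeks,
        arm=arm01,
        participant_id=pid,
        arm_x_spline=arm_x_spline,
    )
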