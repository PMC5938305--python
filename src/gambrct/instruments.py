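"""Scoring of the trial's self-report instruments and the eligibility screen.

Five instruments are supported:

* **NODS** — NORC Diagnostic Screen for Gambling Problems: 17 yes/no items
  mapping onto 10 DSM-IV pathological-gambling criteria, total 0-10.
* **PGSI** — Problem Gambling Severity Index: 9 items, 0-3 each, total 0-27.
  A total of 8 or more denotes problem gambling and is the gambler-side
  inclusion threshold.
* **PHQ-9** — depression: 9 items, 0-3 each, total 0-27.
* **GAD-7** — anxiety: 7 items, 0-3 each, total 0-21.
* **AUDIT** — alcohol use: 10 items, 0-4 each, total 0-40, with sex-specific
  hazardous-use thresholds (strictly above 7 for men, above 5 for women).

Severity bands partition each instrument's total range; ``score_*`` returns a
:class:`ScoredInstrument` carrying the total, the band label, and where
relevant a boolean threshold flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "InstrumentResponse",
    "ScoredInstrument",
    "EligibilityDecision",
    "ParticipantScreen",
    "score_phq9",
    "score_gad7",
    "score_audit",
    "score_nods",
    "score_pgsi",
    "score_items",
    "check_eligibility",
    "INSTRUMENT_SPECS",
    "NODS_CRITERIA",
    "PGSI_PROBLEM_THRESHOLD",
]

PGSI_PROBLEM_THRESHOLD = 8

#: item count, per-item maximum, total maximum for each instrument
INSTRUMENT_SPECS = {
    "NODS": {"n_items": 17, "item_max": 1, "total_max": 10},
    "PGSI": {"n_items": 9, "item_max": 3, "total_max": 27},
    "PHQ9": {"n_items": 9, "item_max": 3, "total_max": 27},
    "GAD7": {"n_items": 7, "item_max": 3, "total_max": 21},
    "AUDIT": {"n_items": 10, "item_max": 4, "total_max": 40},
}

# Severity bands as (low, high, label), inclusive on both ends.  Each table
# partitions [0, total_max] with no gaps or overlaps.
_PHQ9_BANDS = [
    (0, 4, "no depression"),
    (5, 9, "minimal symptoms"),
    (10, 14, "minor depression"),
    (15, 19, "moderately severe major depression"),
    (20, 27, "severe major depression"),
]
_GAD7_BANDS = [
    (0, 4, "no anxiety"),
    (5, 9, "mild anxiety"),
    (10, 14, "moderate anxiety"),
    (15, 21, "severe anxiety"),
]
_NODS_BANDS = [
    (0, 0, "no problematic gambling"),
    (1, 2, "mild subclinical risk"),
    (3, 4, "moderate subclinical gambling problems"),
    (5, 10, "likely pathological gambling"),
]
# Standard PGSI interpretive bands; only the >= 8 problem-gambling threshold
# is used by the trial's eligibility rules.
_PGSI_BANDS = [
    (0, 0, "non-problem gambling"),
    (1, 2, "low risk"),
    (3, 7, "moderate risk"),
    (8, 27, "problem gambling"),
]
# AUDIT zones follow the WHO manual; the trial only uses the hazardous-use
# flag, which is sex-specific and strict (total > 7 men, > 5 women).
_AUDIT_BANDS = [
    (0, 7, "low risk"),
    (8, 15, "hazardous"),
    (16, 19, "harmful"),
    (20, 40, "possible dependence"),
]

# NODS item -> DSM-IV criterion map.  17 items collapse onto 10 criteria;
# 2-item criteria are either OR pairs (endorsing any item scores the
# criterion) or gated pairs (the follow-up item only counts together with its
# gate, e.g. "lied about gambling" only scores when it happened three or more
# times).  Items are 0-indexed.
NODS_CRITERIA = [
    ("preoccupation", (0, 1), "any"),
    ("tolerance", (2,), "any"),
    ("withdrawal", (3, 4), "all"),  # tried to cut down AND restless/irritable
    ("loss_of_control", (5, 6), "any"),
    ("escape", (7, 8), "any"),
    ("chasing", (9,), "any"),
    ("lying", (10, 11), "all"),  # lied AND three or more times
    ("illegal_acts", (12,), "any"),
    ("risked_relationships", (13, 14), "any"),
    ("bailout", (15, 16), "any"),
]


class InstrumentError(ValueError):
    """Raised for malformed item vectors or missing required metadata."""


@dataclass(frozen=True)
class InstrumentResponse:
    """One participant's raw item responses for a single instrument."""

    instrument: str
    items: Sequence[int]
    respondent_role: str = "gambler"  # gambler | cso
    timepoint: str = "pre"  # pre | post | m3 | m6
    sex: str = "unspecified"  # male | female | unspecified; AUDIT only


@dataclass(frozen=True)
class ScoredInstrument:
    instrument: str
    total: int
    category: str
    flag: Optional[bool] = None


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    reasons: tuple = ()

    def __post_init__(self):
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible must be True iff reasons is empty")


@dataclass(frozen=True)
class ParticipantScreen:
    """Screening record for one member of a gambler/CSO pair."""

    pgsi: ScoredInstrument
    age: int
    severe_psychiatric: bool = False


def _validate_items(instrument: str, items: Sequence[int]) -> list:
    spec = INSTRUMENT_SPECS[instrument]
    items = list(items)
    if len(items) != spec["n_items"]:
        raise InstrumentError(
            f"{instrument} expects {spec['n_items']} items, got {len(items)}"
        )
    for i, v in enumerate(items):
        if v != int(v):
            raise InstrumentError(f"{instrument} item {i + 1} is not an integer: {v!r}")
        if not (0 <= v <= spec["item_max"]):
            raise InstrumentError(
                f"{instrument} item {i + 1} out of range 0-{spec['item_max']}: {v}"
            )
    return [int(v) for v in items]


def _band(total: int, bands) -> str:
    for lo, hi, label in bands:
        if lo <= total <= hi:
            return label
    raise InstrumentError(f"total {total} outside band table")


def score_phq9(items: Sequence[int]) -> ScoredInstrument:
    """Score the PHQ-9 depression scale (9 items, 0-3 each)."""
    items = _validate_items("PHQ9", items)
    total = sum(items)
    return ScoredInstrument("PHQ9", total, _band(total, _PHQ9_BANDS))


def score_gad7(items: Sequence[int]) -> ScoredInstrument:
    """Score the GAD-7 anxiety scale (7 items, 0-3 each)."""
    items = _validate_items("GAD7", items)
    total = sum(items)
    return ScoredInstrument("GAD7", total, _band(total, _GAD7_BANDS))


def score_audit(items: Sequence[int], sex: str = "unspecified") -> ScoredInstrument:
    """Score AUDIT; the hazardous-use flag is strict and sex-specific.

    ``flag`` is True for totals above 7 (men) or above 5 (women).  With
    ``sex='unspecified'`` the flag is ``None`` — undefined rather than
    silently False.
    """
    items = _validate_items("AUDIT", items)
    total = sum(items)
    if sex == "male":
        flag = total > 7
    elif sex == "female":
        flag = total > 5
    elif sex == "unspecified":
        flag = None
    else:
        raise InstrumentError(f"unknown sex {sex!r}")
    return ScoredInstrument("AUDIT", total, _band(total, _AUDIT_BANDS), flag)


def score_nods(items: Sequence[int]) -> ScoredInstrument:
    """Score the NODS: 17 binary items collapsed onto 10 DSM-IV criteria.

    Each criterion contributes at most one point; see :data:`NODS_CRITERIA`
    for the gated/OR item structure.
    """
    items = _validate_items("NODS", items)
    total = 0
    for _name, idx, rule in NODS_CRITERIA:
        hits = [items[i] for i in idx]
        met = all(hits) if rule == "all" else any(hits)
        total += int(met)
    return ScoredInstrument("NODS", total, _band(total, _NODS_BANDS))


def score_pgsi(items: Sequence[int]) -> ScoredInstrument:
    """Score the PGSI; ``flag`` marks the problem-gambling threshold (>= 8)."""
    items = _validate_items("PGSI", items)
    total = sum(items)
    return ScoredInstrument(
        "PGSI", total, _band(total, _PGSI_BANDS), total >= PGSI_PROBLEM_THRESHOLD
    )


_SCORERS = {
    "NODS": score_nods,
    "PGSI": score_pgsi,
    "PHQ9": score_phq9,
    "GAD7": score_gad7,
}


def score_items(response: InstrumentResponse) -> ScoredInstrument:
    """Dispatch an :class:`InstrumentResponse` to the matching scorer."""
    if response.instrument == "AUDIT":
        return score_audit(response.items, response.sex)
    try:
        scorer = _SCORERS[response.instrument]
    except KeyError:
        raise InstrumentError(f"unknown instrument {response.instrument!r}") from None
    return scorer(response.items)


def check_eligibility(
    gambler: ParticipantScreen,
    cso: ParticipantScreen,
    relationship_months: float,
) -> EligibilityDecision:
    """Apply the trial's pair-level inclusion rules.

    A pair is eligible iff the gambler screens at or above the PGSI
    problem-gambling threshold, the CSO screens below it, the two have known
    each other for at least three months, both are adults, and neither
    carries a severe-psychiatric exclusion flag.
    """
    missing = [
        name
        for name, rec in (("gambler", gambler), ("cso", cso))
        if rec.pgsi is None or rec.age is None
    ]
    if relationship_months is None:
        missing.append("relationship_months")
    if missing:
        raise InstrumentError(f"missing eligibility fields: {', '.join(missing)}")

    reasons = []
    if gambler.pgsi.total < PGSI_PROBLEM_THRESHOLD:
        reasons.append("gambler_pgsi_below_8")
    if cso.pgsi.total >= PGSI_PROBLEM_THRESHOLD:
        reasons.append("cso_pgsi_problem")
    if relationship_months < 3:
        reasons.append("relationship_under_3_months")
    if gambler.age < 18 or cso.age < 18:
        reasons.append("under_18")
    if gambler.severe_psychiatric or cso.severe_psychiatric:
        reasons.append("severe_psychiatric_flag")
    return EligibilityDecision(eligible=not reasons, reasons=tuple(reasons))
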