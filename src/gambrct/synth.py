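"""Synthetic gambling-trial generators.

Two deliberately separate generators:

* :func:`generate_from_model` draws weekly losses *exactly* from the two-part
  gamma hurdle mixed model at known parameters — the tool for parameter
  recovery and frequentist-coverage studies, where the data must match the
  inference model's assumptions.
* :func:`generate_trial` builds a behaviorally realistic trial: a roster of
  gambler/CSO pairs randomized as units (eligible by construction), daily
  TLFB-G losses structured as abstinence runs punctuated by binge episodes
  (excess zeros, heavy right skew), an abrupt reduction at treatment start,
  questionnaire item tables consistent with configured totals, and optional
  monotone missing-at-random dropout.

Default parameters are calibrated to the scale of an internet-delivered
couples-therapy gambling trial: ~18 pairs, a median-subject marginal loss
near 1000 SEK/day at baseline collapsing to tens of SEK/day after treatment
start, and questionnaire means in the moderate severity bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import instruments as ins
from . import tlfb
from .twopart import TwoPartParams

__all__ = [
    "TrialShape",
    "BingeConfig",
    "DropoutConfig",
    "QuestionnaireTruth",
    "TrialConfig",
    "SyntheticTrial",
    "default_twopart_truth",
    "generate_from_model",
    "generate_trial",
    "apply_dropout",
]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class TrialShape:
    """Shape of an exact-model simulation: subjects, weeks, 1:1 arm split."""

    n_subjects: int = 36
    n_weeks: int = 14  # weeks 0..n_weeks-1; week 0 is baseline

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_weeks < 4:
            raise SynthError("need >= 2 subjects and >= 4 weeks")


def default_twopart_truth(n_coef: int = 7) -> TwoPartParams:
    """Generating parameters matching the study conditions.

    Baseline: occurrence probability ~0.7 and positive-week mean ~1430
    SEK/day, so the median-subject marginal loss is ~1000 SEK/day.  The
    post-baseline jump collapses occurrence to ~0.2 and the mean to ~210
    SEK/day; spline terms add mild continuing decline, and the arm
    interactions are zero (the trial found no between-arm difference).
    """
    beta_occ = np.zeros(n_coef)
    beta_amt = np.zeros(n_coef)
    beta_occ[0], beta_occ[1], beta_occ[2] = 0.85, -2.2, -0.05
    beta_amt[0], beta_amt[1], beta_amt[2] = 7.26, -1.9, -0.04
    return TwoPartParams(
        beta_occ=beta_occ,
        beta_amt=beta_amt,
        shape=0.9,
        sd_occ=1.0,
        sd_amt=0.8,
        rho=0.5,
    )


def _alternating_arms(n: int) -> np.ndarray:
    return np.array(["bct", "cbt"] * ((n + 1) // 2))[:n]


def generate_from_model(
    params: TwoPartParams,
    shape: TrialShape,
    seed: int,
    knots=None,
):
    """Simulate weekly losses exactly from the two-part model.

    Returns ``(weekly, design, truth)`` where ``weekly`` is a participant-week
    table, ``design`` the matching :class:`~gambrct.tlfb.TimeDesign`, and
    ``truth`` echoes ``params`` plus the simulated subject intercepts.
    Identical seed and inputs give identical tables.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n, W = shape.n_subjects, shape.n_weeks
    pids = np.array([f"S{i:03d}" for i in range(n)])
    arms = dict(zip(pids, _alternating_arms(n)))

    weeks = np.tile(np.arange(W, dtype=float), n)
    weekly = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, W),
            "rater": "gambler",
            "week": weeks.astype(int),
            "avg_daily_loss": 0.0,
            "n_days_observed": 7,
        }
    )
    design = tlfb.build_design(weekly, arms, knots=knots)

    L = np.linalg.cholesky(params.cov())
    b = rng.standard_normal((n, 2)) @ L.T
    idx = np.repeat(np.arange(n), W)
    eta_occ = design.X @ params.beta_occ + b[idx, 0]
    eta_amt = design.X @ params.beta_amt + b[idx, 1]
    p = 1.0 / (1.0 + np.exp(-eta_occ))
    z = rng.uniform(size=p.size) < p
    mu = np.exp(eta_amt)
    y = np.where(
        z, rng.gamma(params.shape, 1.0, size=p.size) * mu / params.shape, 0.0
    )
    weekly["avg_daily_loss"] = y
    truth = {"params": params, "intercepts": b, "arms": arms, "seed": seed}
    return weekly, design, truth


# ---------------------------------------------------------------------------
# behavioral generator


@dataclass(frozen=True)
class BingeConfig:
    """Binge-and-abstain daily gambling pattern.

    Baseline behavior alternates abstinence runs (geometric, mean
    ``abstain_mean_days``) with binge episodes of 1-``binge_max_days`` days
    whose daily losses are lognormal with median ``binge_median_loss`` SEK.
    After treatment start, abstinence runs stretch by ``treat_abstain_factor``
    and binge losses shrink by ``treat_loss_factor`` (the abrupt drop); the
    CBT arm multiplies these by ``arm_abstain_factor`` / ``arm_loss_factor``
    (1.0 = no arm difference, as observed).
    """

    abstain_mean_days: float = 4.0
    binge_max_days: int = 3
    binge_median_loss: float = 2000.0
    binge_loss_sigma: float = 1.0
    treat_abstain_factor: float = 6.0
    treat_loss_factor: float = 0.4
    arm_abstain_factor: float = 1.0
    arm_loss_factor: float = 1.0

    def __post_init__(self):
        if self.abstain_mean_days <= 0 or self.binge_max_days < 1:
            raise SynthError("abstinence runs and binges must have positive length")
        if self.binge_median_loss <= 0:
            raise SynthError("binge losses must be positive")


@dataclass(frozen=True)
class DropoutConfig:
    """Monotone MAR dropout: per-week hazard depending only on observed data.

    ``hazard = expit(logit(base_hazard) + loss_slope * log1p(last observed
    weekly loss / 1000))`` — attrition may increase with recent losses, which
    is missing-at-random because it conditions only on *observed* history.
    """

    base_hazard: float = 0.03
    loss_slope: float = 0.0
    start_week: int = 1

    def __post_init__(self):
        if not (0.0 <= self.base_hazard <= 1.0):
            raise SynthError("base hazard must be in [0, 1]")


@dataclass(frozen=True)
class QuestionnaireTruth:
    """Cell means and SDs per (instrument, role, arm) across the four
    assessment timepoints (pre, post, m3, m6)."""

    means: dict = field(
        default_factory=lambda: {
            ("NODS", "gambler", "bct"): [6.9, 3.0, 2.6, 2.2],
            ("NODS", "gambler", "cbt"): [6.4, 2.6, 2.1, 1.5],
            ("PHQ9", "gambler", "bct"): [11.7, 5.2, 6.5, 6.6],
            ("PHQ9", "gambler", "cbt"): [12.3, 5.1, 7.2, 4.3],
            ("PHQ9", "cso", "bct"): [10.2, 4.7, 3.2, 4.1],
            ("PHQ9", "cso", "cbt"): [6.8, 5.0, 10.2, 5.4],
            ("GAD7", "gambler", "bct"): [8.2, 3.9, 2.9, 5.6],
            ("GAD7", "gambler", "cbt"): [8.8, 2.1, 4.3, 2.8],
            ("GAD7", "cso", "bct"): [10.3, 4.7, 4.1, 3.7],
            ("GAD7", "cso", "cbt"): [6.4, 5.1, 8.5, 5.5],
        }
    )
    sd: float = 3.0
    subject_sd: float = 2.0


@dataclass(frozen=True)
class TrialConfig:
    """Full generative description of one synthetic trial."""

    n_pairs: int = 18
    twopart: TwoPartParams = field(default_factory=default_twopart_truth)
    binge: BingeConfig = field(default_factory=BingeConfig)
    dropout: Optional[DropoutConfig] = None
    questionnaires: QuestionnaireTruth = field(default_factory=QuestionnaireTruth)
    baseline_days: int = 30
    n_treat_weeks: int = 10
    followup_weeks: tuple = (tlfb.POST_WEEK, tlfb.M3_WEEK, tlfb.M6_WEEK)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise SynthError("need at least one pair")


@dataclass
class SyntheticTrial:
    roster: pd.DataFrame
    tlfb_daily: pd.DataFrame
    tlfb_weekly: pd.DataFrame
    questionnaires: pd.DataFrame
    truth: dict
    missingness: Optional[pd.DataFrame] = None

    def arms(self) -> dict:
        return dict(zip(self.roster["participant_id"], self.roster["arm"]))

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(outdir / "participants.csv", index=False)
        self.tlfb_daily.to_csv(outdir / "tlfb_daily.csv", index=False)
        self.tlfb_weekly.to_csv(outdir / "tlfb_weekly.csv", index=False)
        self.questionnaires.to_csv(outdir / "questionnaires.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(_jsonable(self.truth), indent=1)
        )


def _jsonable(o):
    """Recursively convert configs/arrays/tuple-keyed dicts to JSON types."""
    if isinstance(o, dict):
        return {
            (k if isinstance(k, str) else "/".join(map(str, np.atleast_1d(k)))):
            _jsonable(v)
            for k, v in o.items()
        }
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if hasattr(o, "__dataclass_fields__"):
        return {f: _jsonable(getattr(o, f)) for f in o.__dataclass_fields__}
    return o


def _draw_items_with_total(rng, total: int, n_items: int, item_max: int) -> np.ndarray:
    """Distribute a total across items respecting per-item maxima: sample
    ``total`` unit slots without replacement from ``n_items * item_max``."""
    slots = np.repeat(np.arange(n_items), item_max)
    chosen = rng.choice(slots.size, size=total, replace=False)
    return np.bincount(slots[chosen], minlength=n_items)


def _nods_items_for_total(rng, total: int) -> np.ndarray:
    """Binary 17-item vector whose criterion score equals ``total``."""
    items = np.zeros(17, dtype=int)
    met = rng.choice(len(ins.NODS_CRITERIA), size=total, replace=False)
    for c in met:
        _, idx, rule = ins.NODS_CRITERIA[c]
        if rule == "all":
            items[list(idx)] = 1
        else:
            items[idx[int(rng.integers(len(idx)))]] = 1
    return items


def _questionnaire_rows(rng, cfg: TrialConfig, roster: pd.DataFrame) -> pd.DataFrame:
    qt = cfg.questionnaires
    timepoints = ["pre", "post", "m3", "m6"]
    rows = []
    subj_dev = {
        pid: rng.normal(0, qt.subject_sd) for pid in roster["participant_id"]
    }
    for _, person in roster.iterrows():
        for (instr, role, arm), means in qt.means.items():
            if person["role"] != role or person["arm"] != arm:
                continue
            spec = ins.INSTRUMENT_SPECS[instr]
            for tp, m in zip(timepoints, means):
                draw = m + subj_dev[person["participant_id"]] + rng.normal(0, qt.sd)
                if instr == "NODS":
                    total = int(np.clip(round(draw), 0, 10))
                    items = _nods_items_for_total(rng, total)
                else:
                    total = int(np.clip(round(draw), 0, spec["total_max"]))
                    items = _draw_items_with_total(
                        rng, total, spec["n_items"], spec["item_max"]
                    )
                row = {
                    "participant_id": person["participant_id"],
                    "role": person["role"],
                    "arm": person["arm"],
                    "instrument": instr,
                    "timepoint": tp,
                }
                row.update({f"item_{i + 1}": v for i, v in enumerate(items)})
                rows.append(row)
    df = pd.DataFrame(rows)
    item_cols = [f"item_{i}" for i in range(1, 18)]
    for c in item_cols:
        if c not in df.columns:
            df[c] = np.nan
    return df


def _binge_series(rng, n_days, abstain_mean, binge_max, loss_median, loss_sigma):
    """Daily losses over ``n_days``: geometric abstinence runs then binges."""
    losses = np.zeros(n_days)
    day = int(rng.geometric(1.0 / max(abstain_mean, 1.0)))
    while day < n_days:
        length = int(rng.integers(1, binge_max + 1))
        for d in range(day, min(day + length, n_days)):
            losses[d] = rng.lognormal(np.log(loss_median), loss_sigma)
        day += length + int(rng.geometric(1.0 / max(abstain_mean, 1.0)))
    return losses


def generate_trial(cfg: TrialConfig) -> SyntheticTrial:
    """Build a behaviorally realistic synthetic trial from a config.

    Gambler/CSO pairs are randomized 1:1 as units; every gambler screens at
    PGSI >= 8 and every CSO below the threshold, so the roster is eligible by
    construction.  Daily TLFB-G series alternate abstinence runs with binge
    episodes; the treatment-start drop and (optional) arm effect act through
    the binge parameters.  Weekly tables come from the same aggregation the
    analysis uses.
    """
    rng = np.random.default_rng(cfg.seed)
    b = cfg.binge

    # roster: pair-level 1:1 randomization with a seeded permuted allocation
    n = cfg.n_pairs
    alloc = np.array(["bct"] * ((n + 1) // 2) + ["cbt"] * (n // 2))
    rng.shuffle(alloc)
    roster_rows = []
    for i in range(n):
        for role in ("gambler", "cso"):
            roster_rows.append(
                {
                    "participant_id": f"P{i:03d}_{'G' if role == 'gambler' else 'C'}",
                    "pair_id": f"P{i:03d}",
                    "role": role,
                    "arm": alloc[i],
                    "age": int(rng.integers(18, 65)),
                    "sex": str(rng.choice(["male", "female"])),
                    "screening_pgsi": int(
                        rng.integers(8, 28) if role == "gambler" else rng.integers(0, 8)
                    ),
                    "relationship_months": int(rng.integers(3, 240)),
                }
            )
    roster = pd.DataFrame(roster_rows)

    # daily TLFB-G per gambler: baseline month then treatment + follow-ups
    last_week = max(cfg.followup_weeks)
    daily_rows = []
    observed_weeks = sorted(
        {0, *range(1, cfg.n_treat_weeks + 1), *cfg.followup_weeks}
    )
    for i in range(n):
        pid = f"P{i:03d}_G"
        arm = alloc[i]
        arm_f = (b.arm_abstain_factor, b.arm_loss_factor) if arm == "cbt" else (1.0, 1.0)
        base = _binge_series(
            rng, cfg.baseline_days, b.abstain_mean_days, b.binge_max_days,
            b.binge_median_loss, b.binge_loss_sigma,
        )
        for d, loss in enumerate(base):
            daily_rows.append((pid, "gambler", d - cfg.baseline_days, loss))
        post = _binge_series(
            rng,
            7 * last_week,
            b.abstain_mean_days * b.treat_abstain_factor * arm_f[0],
            b.binge_max_days,
            b.binge_median_loss * b.treat_loss_factor * arm_f[1],
            b.binge_loss_sigma,
        )
        for d, loss in enumerate(post):
            week = d // 7 + 1
            if week in observed_weeks:
                daily_rows.append((pid, "gambler", d, loss))
        # CSO-rated series: the gambler's losses observed with noise and
        # occasional under-reporting of small binges
        cid = f"P{i:03d}_C"
        for p, r, d, loss in [r for r in daily_rows if r[0] == pid]:
            seen = loss if (loss == 0 or rng.uniform() > 0.2) else 0.0
            noisy = seen * rng.lognormal(0, 0.15) if seen > 0 else 0.0
            daily_rows.append((cid, "cso", d, noisy))

    daily = pd.DataFrame(
        daily_rows, columns=["participant_id", "rater", "study_day", "net_loss"]
    )
    daily, _ = tlfb.ingest_daily(daily, clamp_negative=True)
    weekly = tlfb.aggregate_weekly(daily)

    questionnaires = _questionnaire_rows(rng, cfg, roster)

    trial = SyntheticTrial(
        roster=roster,
        tlfb_daily=daily,
        tlfb_weekly=weekly,
        questionnaires=questionnaires,
        truth={
            "config": cfg,
            "allocation": dict(zip([f"P{i:03d}" for i in range(n)], alloc)),
        },
    )
    if cfg.dropout is not None:
        trial = apply_dropout(trial, cfg.dropout, cfg.seed + 1)
    return trial


def apply_dropout(
    trial: SyntheticTrial, dropout: DropoutConfig, seed: int
) -> SyntheticTrial:
    """Impose monotone MAR dropout on a synthetic trial.

    Each pair faces a per-week dropout hazard from ``DropoutConfig``; once a
    pair drops at week w, all its records (daily, weekly, questionnaires)
    after w are removed.  Returns a new trial with a missingness table
    attached; the input is not modified.
    """
    from scipy.special import expit, logit

    if not (0.0 <= dropout.base_hazard <= 1.0):
        raise SynthError("hazard must be in [0, 1]")
    rng = np.random.default_rng(seed)
    weekly = trial.tlfb_weekly
    gambler_weekly = weekly[weekly["rater"] == "gambler"]
    pair_of = dict(zip(trial.roster["participant_id"], trial.roster["pair_id"]))

    drop_week = {}
    miss_rows = []
    base_logit = logit(np.clip(dropout.base_hazard, 1e-9, 1 - 1e-9))
    for pair, group in trial.roster.groupby("pair_id"):
        gid = group.loc[group["role"] == "gambler", "participant_id"].iloc[0]
        series = gambler_weekly[gambler_weekly["participant_id"] == gid].sort_values("week")
        weeks = series["week"].tolist()
        losses = series["avg_daily_loss"].tolist()
        dropped = None
        for j, w in enumerate(weeks):
            if w < dropout.start_week:
                continue
            last_loss = losses[j - 1] if j > 0 else 0.0
            hz = expit(base_logit + dropout.loss_slope * np.log1p(last_loss / 1000.0))
            if rng.uniform() < hz:
                dropped = w
                break
        drop_week[pair] = dropped
        miss_rows.append({"pair_id": pair, "dropout_week": dropped})

    def keep_weekly(df):
        wk = df["participant_id"].map(pair_of).map(drop_week)
        return df[wk.isna() | (df["week"] < wk.astype(float))].reset_index(drop=True)

    def keep_daily(df):
        wk = df["participant_id"].map(pair_of).map(drop_week)
        day_week = df["study_day"].map(lambda d: 0 if d < 0 else d // 7 + 1)
        return df[wk.isna() | (day_week < wk.astype(float))].reset_index(drop=True)

    tp_week = {"pre": 0, "post": tlfb.POST_WEEK, "m3": tlfb.M3_WEEK, "m6": tlfb.M6_WEEK}

    def keep_q(df):
        wk = df["participant_id"].map(pair_of).map(drop_week)
        tw = df["timepoint"].map(tp_week)
        return df[wk.isna() | (tw < wk.astype(float))].reset_index(drop=True)

    return SyntheticTrial(
        roster=trial.roster.copy(),
        tlfb_daily=keep_daily(trial.tlfb_daily),
        tlfb_weekly=keep_weekly(trial.tlfb_weekly),
        questionnaires=keep_q(trial.questionnaires),
        truth=dict(trial.truth),
        missingness=pd.DataFrame(miss_rows),
    )
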