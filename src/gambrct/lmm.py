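"""Bayesian linear mixed models for the questionnaire outcomes.

NODS, PHQ-9 and GAD-7 totals are modeled with a Gaussian likelihood, time as
a categorical variable (pre, post, m3, m6), an arm main effect, arm x time
interactions, and subject-specific random intercepts.  Unlike the loss
model, the arm difference at baseline is freely estimated (the design has an
arm main-effect column): the assessment tables report a pre-treatment
difference from the reference arm.

The subject intercept is integrated out analytically (the per-subject
marginal is multivariate normal with compound-symmetric covariance
``sigma^2 I + tau^2 J``), and the low-dimensional posterior is sampled with
the same ensemble-MCMC machinery as the two-part model.  Priors mirror that
model: Normal(0, 10^2) on coefficients, half-Student-t(3, 0, 2.5) on both
SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .posterior import EffectSummary, PosteriorDraws, summarize_draws
from .twopart import McmcConfig, TwoPartPriors, _diagnostics, _run_ensemble, _thin_chain

__all__ = ["TIMEPOINTS", "fit_lmm", "lmm_change"]

TIMEPOINTS = ["pre", "post", "m3", "m6"]


class LmmError(ValueError):
    pass


def _lmm_design(df: pd.DataFrame):
    """Treatment-coded design: intercept, time dummies, arm, arm x time."""
    tps = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    if len(tps) < 2:
        raise LmmError("need at least two timepoints to fit a time effect")
    if tps[0] != "pre":
        raise LmmError("baseline timepoint 'pre' is required")
    arm01 = df["arm"].map({"bct": 0.0, "cbt": 1.0})
    if arm01.isna().any():
        raise LmmError(f"unknown arm labels: {sorted(set(df['arm']) - {'bct', 'cbt'})}")
    cols = {"intercept": np.ones(len(df))}
    for t in tps[1:]:
        cols[f"time_{t}"] = (df["timepoint"] == t).astype(float)
    cols["arm"] = arm01.to_numpy()
    for t in tps[1:]:
        cols[f"arm:time_{t}"] = cols[f"time_{t}"] * cols["arm"]
    X = pd.DataFrame(cols)
    empty = [
        (a, t)
        for a in ("bct", "cbt")
        for t in tps
        if not ((df["arm"] == a) & (df["timepoint"] == t)).any()
    ]
    return X, tps, empty


class _LmmPosterior:
    """Vectorized log posterior with the subject intercept integrated out.

    Parameters: [beta (K), log sigma (residual SD), log tau (intercept SD)].
    Per-subject marginal covariance is sigma^2 I + tau^2 J, handled in
    closed form via the rank-one Woodbury identity.
    """

    def __init__(self, y, X, subject_ids, priors: TwoPartPriors):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.K = X.shape[1]
        self.n_params = self.K + 2
        subjects, idx = np.unique(subject_ids, return_inverse=True)
        S = subjects.size
        self.subjects = subjects
        self.n_obs = np.bincount(idx, minlength=S).astype(float)
        self.yy = np.bincount(idx, weights=y * y, minlength=S)
        self.sum_y = np.bincount(idx, weights=y, minlength=S)
        self.Xty = np.stack(
            [np.bincount(idx, weights=X[:, k] * y, minlength=S) for k in range(self.K)],
            axis=1,
        )  # (S, K)
        self.sum_X = np.stack(
            [np.bincount(idx, weights=X[:, k], minlength=S) for k in range(self.K)],
            axis=1,
        )
        self.XtX = np.einsum("nk,nl,ns->skl", X, X, np.eye(S)[idx])
        self.priors = priors
        self.y, self.X, self.idx = y, X, idx

    def __call__(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        beta = theta[:, : self.K]  # (B, K)
        log_sig, log_tau = theta[:, self.K], theta[:, self.K + 1]
        sig2, tau2 = np.exp(2 * log_sig), np.exp(2 * log_tau)
        # per-subject residual sums
        rss = (
            self.yy[None, :]
            - 2 * np.einsum("bk,sk->bs", beta, self.Xty)
            + np.einsum("bk,skl,bl->bs", beta, self.XtX, beta)
        )
        rsum = self.sum_y[None, :] - np.einsum("bk,sk->bs", beta, self.sum_X)
        n = self.n_obs[None, :]
        denom = sig2[:, None] + n * tau2[:, None]
        quad = (rss - tau2[:, None] * rsum**2 / denom) / sig2[:, None]
        logdet = (n - 1) * 2 * log_sig[:, None] + np.log(denom)
        ll = -0.5 * np.sum(quad + logdet + n * np.log(2 * np.pi), axis=1)

        pr = self.priors
        sig, tau = np.exp(log_sig), np.exp(log_tau)
        lp = -0.5 * np.sum(beta**2, axis=1) / pr.beta_sd**2
        for s, ls in ((sig, log_sig), (tau, log_tau)):
            lp += (
                -0.5 * (pr.sd_df + 1) * np.log1p(s**2 / (pr.sd_df * pr.sd_scale**2))
                + ls
            )
        out = ll + lp
        return np.where(np.isfinite(out), out, -1e300)

    def neg_with_grad(self, theta, eps=1e-6):
        theta = np.asarray(theta, dtype=float)
        P = theta.size
        pts = np.vstack([theta, theta + eps * np.eye(P), theta - eps * np.eye(P)])
        vals = self(pts)
        return -vals[0], -(vals[1 : P + 1] - vals[P + 1 :]) / (2 * eps)


def fit_lmm(
    outcomes: pd.DataFrame,
    config: Optional[McmcConfig] = None,
    seed: Optional[int] = None,
    priors: Optional[TwoPartPriors] = None,
) -> PosteriorDraws:
    """Fit the categorical-time LMM to one instrument's total scores.

    ``outcomes`` needs columns participant_id, arm, timepoint, total (one
    instrument, one role at a time).  Missing timepoints are simply absent
    rows (MAR).  Empty arm x timepoint cells raise a warning listing them.
    """
    if seed is None:
        raise LmmError("a seed is required for reproducible sampling")
    config = config or McmcConfig(n_quad=1)
    priors = priors or TwoPartPriors()
    df = outcomes.reset_index(drop=True)
    dup = df.duplicated(["participant_id", "timepoint"])
    if dup.any():
        raise LmmError("multiple rows per participant x timepoint")
    Xdf, tps, empty = _lmm_design(df)
    if empty:
        warnings.warn(f"empty arm x timepoint cells: {empty}", stacklevel=2)
    post = _LmmPosterior(df["total"], Xdf.to_numpy(), df["participant_id"], priors)
    names = list(Xdf.columns) + ["sigma", "tau"]

    rng = np.random.default_rng(seed)
    theta0 = np.zeros(post.n_params)
    theta0[0] = float(df["total"].mean())
    theta0[post.K :] = np.log(max(float(df["total"].std() or 1.0), 0.5))
    res = optimize.minimize(
        post.neg_with_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 300},
    )
    n_walkers = max(config.n_walkers, 2 * post.n_params + 2)

    def make_starts(_e):
        return res.x[None, :] + 0.05 * rng.standard_normal((n_walkers, post.n_params))

    chains_list, acc = _run_ensemble(post, make_starts, config, seed)
    diag = _diagnostics(chains_list, names, acc, config.rhat_gate)
    flat, chains, draws = _thin_chain(chains_list, config.max_draws)
    table = pd.DataFrame(flat, columns=names)
    table["sigma"] = np.exp(table["sigma"])
    table["tau"] = np.exp(table["tau"])
    table.insert(0, "draw", draws)
    table.insert(0, "chain", chains)
    return PosteriorDraws(
        table=table,
        param_names=names,
        diagnostics=diag,
        subjects=post.subjects,
        config={"timepoints": tps, "seed": seed},
    )


def _cell_mean_draws(draws: PosteriorDraws, arm: str, timepoint: str) -> np.ndarray:
    a = {"bct": 0.0, "cbt": 1.0}[arm]
    tps = draws.config["timepoints"]
    if timepoint not in tps:
        raise LmmError(f"unknown timepoint {timepoint!r}; fitted: {tps}")
    m = draws.column("intercept") + a * draws.column("arm")
    if timepoint != "pre":
        m = m + draws.column(f"time_{timepoint}") + a * draws.column(f"arm:time_{timepoint}")
    return m


def lmm_change(draws: PosteriorDraws, arm: str, timepoint: str) -> dict:
    """Within-arm change from baseline and the between-arm difference.

    Returns EffectSummary entries mirroring the assessment-table layout:
    ``change`` is (timepoint - pre) within ``arm``; ``diff_from_bct`` is the
    CBT - BCT difference of the cell means at ``timepoint``.
    """
    cell = _cell_mean_draws(draws, arm, timepoint)
    base = _cell_mean_draws(draws, arm, "pre")
    diff = _cell_mean_draws(draws, "cbt", timepoint) - _cell_mean_draws(
        draws, "bct", timepoint
    )
    return {
        "cell": summarize_draws(cell, f"{arm} {timepoint}", "score points"),
        "change": summarize_draws(cell - base, f"{arm} {timepoint} - pre", "score points"),
        "diff_from_bct": summarize_draws(diff, f"{timepoint} CBT - BCT", "score points"),
    }
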