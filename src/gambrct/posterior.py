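"""Posterior-draw containers and interval summaries shared by all models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws", "EffectSummary", "summarize_draws"]


@dataclass(frozen=True)
class EffectSummary:
    """Posterior median and equal-tailed 95% credible interval for one effect."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    scale: str = ""
    warnings: tuple = ()

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"{self.label}: estimate {self.estimate} outside "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def summarize_draws(values, label: str, scale: str = "", warn: tuple = ()) -> EffectSummary:
    """Median + equal-tailed 95% percentile interval of a draw vector."""
    v = np.asarray(values, dtype=float)
    lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
    return EffectSummary(label, float(med), float(lo), float(hi), scale, tuple(warn))


@dataclass
class PosteriorDraws:
    """Labeled MCMC draws with chain metadata and sampler diagnostics.

    ``table`` has one row per retained draw with columns ``chain``, ``draw``
    and one column per parameter.  ``intercepts`` (optional) holds per-subject
    random intercepts sampled for a subset of draws, shaped
    ``(n_draws_sub, n_subjects, 2)`` for the two-part model or
    ``(n_draws_sub, n_subjects)`` for the LMM, with ``intercept_draw_idx``
    giving the corresponding rows of ``table``.  ``diagnostics`` carries
    split R-hat and effective sample size per parameter, the ensemble
    acceptance rate, and any convergence warnings; ``divergences`` is None
    because the ensemble sampler has no divergence concept.
    """

    table: pd.DataFrame
    param_names: list
    diagnostics: dict = field(default_factory=dict)
    subjects: Optional[np.ndarray] = None
    intercepts: Optional[np.ndarray] = None
    intercept_draw_idx: Optional[np.ndarray] = None
    design: object = None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.table) < 1:
            raise ValueError("posterior must contain at least one draw")

    @property
    def n_draws(self) -> int:
        return len(self.table)

    def params(self, names=None) -> np.ndarray:
        """Draws as an (n_draws, n_params) array in ``names`` order."""
        return self.table[list(names or self.param_names)].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def ci(self, name: str, level: float = 0.95):
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.column(name), [a, 100 - a])
        return float(lo), float(hi)

    @property
    def max_rhat(self) -> float:
        rhat = self.diagnostics.get("rhat", {})
        return max(rhat.values()) if rhat else float("nan")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
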