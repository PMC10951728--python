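"""Condition-level inference: repeated-measures ANOVA and Sidak post hocs.

Each outcome is tested with a one-way repeated-measures ANOVA (hopping
condition as the fixed within-subject factor, participant as the random
effect).  For a complete balanced design this classical decomposition is
identical to the mixed-model route: the error term is the condition x
participant interaction, F = MS_condition / MS_interaction with
(k-1, (k-1)(n-1)) degrees of freedom.  Significant main effects are
followed by all pairwise paired t-tests with a Sidak correction,
p_adj = 1 - (1 - p)^m over the m = k(k-1)/2 comparisons.

Sphericity corrections are not applied by default; a Greenhouse–Geisser
epsilon adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "AnovaResult",
    "rm_anova",
    "posthoc_sidak",
    "sidak_adjust",
    "simulate_null_outcomes",
]


class IncompleteDesignError(ValueError):
    """The participant x condition design has missing cells."""


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ss_condition: float
    ss_error: float
    gg_epsilon: Optional[float] = None

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _pivot(table: pd.DataFrame, dv: str, within: str, subject: str) -> pd.DataFrame:
    counts = table.groupby([subject, within])[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise IncompleteDesignError(
            "every participant must contribute exactly one value per condition"
        )
    return table.pivot(index=subject, columns=within, values=dv)


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "participant",
    gg_correction: bool = False,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a long-format table.

    Requires a complete crossed design (no silent imputation); with all
    condition means equal the F statistic is exactly 0.
    """
    wide = _pivot(table, dv, within, subject)
    y = wide.to_numpy(float)
    n, k = y.shape
    if k < 2 or n < 2:
        raise IncompleteDesignError("need >= 2 conditions and >= 2 participants")

    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj

    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    eps = None
    if ss_cond <= 0:
        f, p = 0.0, 1.0
    elif ms_err <= 0:
        f, p = np.inf, 0.0
    else:
        f = ms_cond / ms_err
        if gg_correction:
            eps = _gg_epsilon(y)
            p = float(sst.f.sf(f, eps * df1, eps * df2))
        else:
            p = float(sst.f.sf(f, df1, df2))
    return AnovaResult(
        F=float(f), df1=df1, df2=df2, p=p,
        ss_condition=float(ss_cond), ss_error=float(ss_err), gg_epsilon=eps,
    )


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity epsilon from the sample covariance."""
    k = y.shape[1]
    S = np.cov(y, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def sidak_adjust(p: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m."""
    p = np.asarray(p, float)
    m = m if m is not None else p.size
    return 1.0 - (1.0 - p) ** m


def posthoc_sidak(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "participant",
    alpha: float = 0.05,
    gate: bool = True,
) -> pd.DataFrame:
    """All pairwise paired t-tests with Sidak-adjusted p-values.

    By default the tests run only when the RM-ANOVA main effect is
    significant at ``alpha`` (an empty table is returned otherwise); pass
    ``gate=False`` to run them regardless.  Zero-variance difference
    scores yield exact p = 1 (zero mean difference) or p = 0.
    """
    anova = rm_anova(table, dv, within, subject)
    cols = ["a", "b", "mean_diff", "t", "p_raw", "p_sidak"]
    if gate and not anova.significant:
        return pd.DataFrame(columns=cols)
    wide = _pivot(table, dv, within, subject)
    pairs = list(combinations(sorted(wide.columns), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = wide[a].to_numpy(float) - wide[b].to_numpy(float)
        if np.allclose(diff.std(ddof=1), 0.0):
            t = 0.0 if np.allclose(diff.mean(), 0.0) else np.inf * np.sign(diff.mean())
            p_raw = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
        else:
            t, p_raw = sst.ttest_rel(wide[a], wide[b])
        rows.append(
            {"a": a, "b": b, "mean_diff": float(diff.mean()), "t": float(t),
             "p_raw": float(p_raw), "p_sidak": float(sidak_adjust(np.array([p_raw]), m)[0])}
        )
    return pd.DataFrame(rows, columns=cols)


def simulate_null_outcomes(
    n_participants: int,
    conditions: Sequence[str],
    sd_subject: float = 1.0,
    sd_noise: float = 0.3,
    effects: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Outcome-level cohort table: participant random effect + residual
    noise (+ optional per-condition shifts).  With zero effects this is the
    null model used to audit the ANOVA's type-I error calibration."""
    rng = rng or np.random.default_rng()
    effects = effects or {}
    rows = []
    subj = rng.normal(0.0, sd_subject, n_participants)
    for i in range(n_participants):
        for cond in conditions:
            rows.append(
                {
                    "participant": i,
                    "condition": cond,
                    "value": subj[i] + effects.get(cond, 0.0)
                    + rng.normal(0.0, sd_noise),
                }
            )
    return pd.DataFrame(rows)
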