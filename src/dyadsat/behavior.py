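"""Session-level behavioral statistics.

One-way repeated-measures ANOVA (within-subject factor: session) on
pair-level satisfaction, with partial and generalized eta squared, and
Shaffer-corrected paired-t post-hoc comparisons for the three-session case.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats

__all__ = ["rm_anova", "shaffer_posthoc", "AnovaResult", "PosthocResult"]


@dataclass
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_p_sq: float
    eta_G_sq: float
    gg_epsilon: float | None = None  # set when sphericity-corrected


@dataclass
class PosthocResult:
    comparisons: list  # (i, j) session index pairs, 0-based
    t_values: np.ndarray
    p_values: np.ndarray  # raw two-sided paired-t p
    thresholds: np.ndarray  # Shaffer per-step alpha, in ascending-p order
    significant: np.ndarray  # bool per comparison (original order)
    alpha: float


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-D (subjects/pairs x sessions)")
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 sessions")
    if not np.all(np.isfinite(scores)):
        raise ValueError("missing or non-finite cells are not supported")
    return scores


def rm_anova(scores: np.ndarray, sphericity_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a P×S complete score table.

    Classical within-subject decomposition
    ``SS_total = SS_subject + SS_effect + SS_error`` with
    ``F = MS_effect / MS_error`` on (S-1, (P-1)(S-1)) degrees of freedom.
    Effect sizes: partial eta squared ``SS_e / (SS_e + SS_err)`` and
    generalized eta squared ``SS_e / (SS_e + SS_subj + SS_err)``.

    ``sphericity_correction=True`` applies the Greenhouse–Geisser epsilon to
    the degrees of freedom of the p-value (the F statistic is unchanged).
    """
    scores = _check_scores(scores)
    p, s = scores.shape
    grand = scores.mean()
    subj_means = scores.mean(axis=1)
    sess_means = scores.mean(axis=0)
    ss_subject = s * np.sum((subj_means - grand) ** 2)
    ss_effect = p * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_effect
    df_effect = s - 1
    df_error = (p - 1) * (s - 1)
    ms_error = ss_error / df_error
    if ms_error <= np.finfo(float).eps * max(1.0, ss_total):
        raise ValueError("zero error variance; F statistic is undefined")
    F = (ss_effect / df_effect) / ms_error

    gg_eps = None
    de, dr = float(df_effect), float(df_error)
    if sphericity_correction:
        gg_eps = _greenhouse_geisser_epsilon(scores)
        de *= gg_eps
        dr *= gg_eps
    p_value = float(scipy.stats.f.sf(F, de, dr))
    return AnovaResult(
        F=float(F),
        df_effect=de,
        df_error=dr,
        p=p_value,
        eta_p_sq=float(ss_effect / (ss_effect + ss_error)),
        eta_G_sq=float(ss_effect / (ss_effect + ss_subject + ss_error)),
        gg_epsilon=gg_eps,
    )


def _greenhouse_geisser_epsilon(scores: np.ndarray) -> float:
    s = scores.shape[1]
    cov = np.cov(scores, rowvar=False)
    dc = cov - cov.mean(axis=0)[None, :] - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(dc) ** 2
    den = (s - 1) * np.sum(dc**2)
    return float(num / den)


def shaffer_posthoc(
    scores: np.ndarray, alpha: float = 0.05
) -> PosthocResult:
    """All pairwise paired t-tests with Shaffer's sequential correction.

    Implemented for exactly three sessions, where the logical structure of
    the three pairwise equalities gives per-step thresholds
    (alpha/3, alpha, alpha): if all three means could be equal at most 3
    hypotheses are true, but once any one is rejected at most 1 can remain
    true.  The procedure is sequentially rejective on ascending p-values
    and stops at the first non-rejection.
    """
    scores = _check_scores(scores)
    s = scores.shape[1]
    if s != 3:
        raise ValueError(
            "Shaffer post-hoc is implemented for exactly 3 sessions"
        )
    comps = list(combinations(range(s), 2))
    t_vals = np.empty(len(comps))
    p_vals = np.empty(len(comps))
    for idx, (i, j) in enumerate(comps):
        t_vals[idx], p_vals[idx] = scipy.stats.ttest_rel(
            scores[:, i], scores[:, j]
        )
    order = np.argsort(p_vals)
    thresholds = np.array([alpha / 3.0, alpha, alpha])
    significant = np.zeros(len(comps), dtype=bool)
    for step, idx in enumerate(order):
        if p_vals[idx] <= thresholds[step]:
            significant[idx] = True
        else:
            break  # sequentially rejective: stop at first failure
    return PosthocResult(
        comparisons=comps,
        t_values=t_vals,
        p_values=p_vals,
        thresholds=thresholds,
        significant=significant,
        alpha=alpha,
    )
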