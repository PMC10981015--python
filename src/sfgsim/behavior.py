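"""Behavioral measures and statistics for the figure-detection task.

Implements the paradigm's standard analysis chain: per-participant hit/false-alarm
rates, the sensitivity index d' with an extreme-rate correction, mean
reaction times, split-plot (mixed-design) ANOVA with a 2-level within
factor and partial eta squared, Tukey-Kramer post hoc comparisons, and
Bonferroni-corrected Pearson correlations.

The mixed ANOVA exploits the 2-level within structure exactly: the
between-subjects effect is tested on per-subject condition means against
the subjects-within-groups error, while the within effect and the
interaction are tested on per-subject condition differences.  Unbalanced
groups are handled with effect-coded Type III tests (the within main
effect is the unweighted mean of the group difference-means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (InvalidParameterError, MissingCellError,
                     UndefinedStatisticError)

__all__ = [
    "TrialRecord",
    "summarize_session",
    "dprime",
    "corrected_rate",
    "mixed_anova",
    "one_way_anova",
    "partial_eta_squared",
    "tukey_kramer",
    "pearson_bonferroni",
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
]


@dataclass(frozen=True)
class TrialRecord:
    participant: str
    condition: str   # "LN" | "HN"
    figure: bool
    response_yes: bool
    rt_ms: float
    block: int = 0


def _trials_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([t.__dict__ for t in trials])


def corrected_rate(count: int, n: int) -> float:
    """Rate with the 1/(2N) correction pulling counts half a trial toward
    chance, guaranteeing finite z-transforms for perfect scores."""
    if n <= 0:
        raise InvalidParameterError("need a positive trial count")
    if count > n / 2:
        return (count - 0.5) / n
    if count < n / 2:
        return (count + 0.5) / n
    return 0.5


def dprime(hits: int, n_fig: int, fas: int, n_nofig: int) -> float:
    """Sensitivity index d' = z(hit rate) - z(false-alarm rate)."""
    if n_fig <= 0 or n_nofig <= 0:
        raise InvalidParameterError("both trial types need at least one trial")
    h = corrected_rate(hits, n_fig)
    f = corrected_rate(fas, n_nofig)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def summarize_session(trials, rt_trials: str = "hits") -> pd.DataFrame:
    """Per participant x condition: hit rate, FA rate, d', mean RT.

    ``rt_trials`` selects which trials enter the RT mean: ``"hits"``
    (default) or ``"correct"`` (hits plus correct rejections).
    """
    df = _trials_frame(trials)
    rows = []
    for (pid, cond), cell in df.groupby(["participant", "condition"], sort=True):
        fig = cell[cell["figure"]]
        nofig = cell[~cell["figure"]]
        if len(fig) == 0 or len(nofig) == 0:
            raise MissingCellError(
                f"participant {pid} condition {cond} lacks figure or "
                f"no-figure trials")
        hits = int(fig["response_yes"].sum())
        fas = int(nofig["response_yes"].sum())
        if rt_trials == "hits":
            rt_cell = fig[fig["response_yes"]]
        elif rt_trials == "correct":
            rt_cell = pd.concat([fig[fig["response_yes"]],
                                 nofig[~nofig["response_yes"]]])
        else:
            raise InvalidParameterError(f"unknown rt_trials {rt_trials!r}")
        rows.append({
            "participant": pid, "condition": cond,
            "hit_rate": hits / len(fig), "fa_rate": fas / len(nofig),
            "dprime": dprime(hits, len(fig), fas, len(nofig)),
            "mean_rt_ms": float(rt_cell["rt_ms"].mean()) if len(rt_cell) else np.nan,
            "n_figure": len(fig), "n_nofigure": len(nofig),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA

@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """eta_p^2 = F df1 / (F df1 + df2)."""
    return F * df1 / (F * df1 + df2)


def _effect_codes(groups: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(groups.unique())
    g = len(levels)
    codes = np.zeros((len(groups), g - 1))
    for j, lev in enumerate(levels[:-1]):
        codes[:, j] = np.where(groups == lev, 1.0,
                               np.where(groups == levels[-1], -1.0, 0.0))
    return codes, levels


def _glm_f_tests(y: np.ndarray, codes: np.ndarray):
    """Type III F tests for the intercept and the coded factor in
    y ~ 1 + codes, via residual-sum-of-squares comparisons."""
    n = len(y)
    X_full = np.column_stack([np.ones(n), codes])
    q_factor = codes.shape[1]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(X_full)
    df_err = n - X_full.shape[1]
    rss_no_int = rss(codes) if q_factor else float(y @ y)
    rss_no_fac = rss(np.ones((n, 1)))
    ms_err = rss_full / df_err

    def f_ratio(ss_effect, df_effect):
        ms = ss_effect / df_effect
        if ms_err == 0:  # degenerate: no residual variance
            return np.inf if ms > 1e-12 else 0.0
        return ms / ms_err

    f_int = f_ratio(rss_no_int - rss_full, 1.0)
    f_fac = f_ratio(rss_no_fac - rss_full, q_factor) if q_factor else np.nan
    return f_int, f_fac, q_factor, df_err, ms_err


def mixed_anova(data, dv: str = "value", within: str = "condition",
                between: str = "group", subject: str = "participant",
                within_levels: tuple[str, str] | None = None
                ) -> list[AnovaResult]:
    """Split-plot ANOVA with one 2-level within factor and one between factor.

    Every subject must contribute exactly one value per within level.
    Returns results for the between main effect, the within main effect,
    and their interaction, each with partial eta squared.
    """
    df = pd.DataFrame(data)
    levels = (sorted(df[within].unique()) if within_levels is None
              else list(within_levels))
    if len(levels) != 2:
        raise InvalidParameterError("the within factor must have 2 levels")
    wide = df.pivot_table(index=[subject, between], columns=within,
                          values=dv, aggfunc="mean")
    if wide[levels].isna().any().any():
        raise MissingCellError("a subject is missing a within-factor level")
    wide = wide.reset_index()
    groups = wide[between]
    n_levels = sorted(groups.unique())
    if any((groups == g).sum() < 2 for g in n_levels):
        raise InvalidParameterError("each group needs at least 2 subjects")
    m = wide[levels].mean(axis=1).to_numpy()          # subject means
    d = (wide[levels[0]] - wide[levels[1]]).to_numpy()  # within differences
    codes, _ = _effect_codes(groups)

    out = []
    # between-subjects effect, tested on subject means
    if codes.shape[1]:
        _, f_b, q_b, df_b, _ = _glm_f_tests(m, codes)
        out.append(AnovaResult(between, float(f_b), q_b, df_b,
                               float(stats.f.sf(f_b, q_b, df_b)),
                               partial_eta_squared(f_b, q_b, df_b)))
    # within effect and interaction, tested on difference scores
    f_w, f_int, q_i, df_w, _ = _glm_f_tests(d, codes)
    out.append(AnovaResult(within, float(f_w), 1, df_w,
                           float(stats.f.sf(f_w, 1, df_w)),
                           partial_eta_squared(f_w, 1, df_w)))
    if codes.shape[1]:
        out.append(AnovaResult(f"{between}*{within}", float(f_int), q_i, df_w,
                               float(stats.f.sf(f_int, q_i, df_w)),
                               partial_eta_squared(f_int, q_i, df_w)))
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """Between-subjects one-way ANOVA with partial eta squared."""
    df = pd.DataFrame({"y": values, "g": groups})
    samples = [cell["y"].to_numpy() for _, cell in df.groupby("g")]
    if len(samples) < 2:
        raise InvalidParameterError("need at least two groups")
    F, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = len(df) - len(samples)
    return AnovaResult("group", float(F), df1, df2, float(p),
                       partial_eta_squared(float(F), df1, df2))


# ---------------------------------------------------------------------------
# Post hoc and correlations

@dataclass(frozen=True)
class PosthocResult:
    pair: tuple
    q: float
    p: float
    mean_diff: float


def tukey_kramer(means, ns, ms_error: float, df_error: int
                 ) -> list[PosthocResult]:
    """Tukey-Kramer pairwise comparisons from cell means.

    The studentized-range statistic for unequal cell sizes uses
    SE = sqrt(MS_error/2 * (1/n_i + 1/n_j)); p-values come from the
    studentized range distribution with k groups and df_error degrees of
    freedom.
    """
    if df_error <= 0:
        raise InvalidParameterError("df_error must be positive")
    means = {k: float(v) for k, v in (means.items() if isinstance(means, dict)
                                      else enumerate(means))}
    ns = {k: int(v) for k, v in (ns.items() if isinstance(ns, dict)
                                 else enumerate(ns))}
    keys = list(means)
    if len(keys) < 2:
        raise InvalidParameterError("need at least two cells")
    k = len(keys)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = keys[i], keys[j]
            diff = means[a] - means[b]
            se = math.sqrt(ms_error / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_error)) if q > 0 else 1.0
            out.append(PosthocResult(pair=(a, b), q=float(q), p=min(p, 1.0),
                                     mean_diff=float(diff)))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple
    r: float
    p: float
    p_adjusted: float
    n: int


def pearson_bonferroni(pairs: dict, m: int | None = None
                       ) -> list[CorrelationResult]:
    """Pearson correlations with Bonferroni adjustment over `m` tests.

    ``pairs`` maps a label to an ``(x, y)`` tuple; ``m`` defaults to the
    number of pairs.
    """
    if m is None:
        m = len(pairs)
    out = []
    for label, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise InvalidParameterError(f"pair {label!r}: need n >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            raise UndefinedStatisticError(
                f"pair {label!r}: zero variance, r undefined")
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(pair=label, r=float(r), p=float(p),
                                     p_adjusted=min(1.0, m * float(p)),
                                     n=len(x)))
    return out
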