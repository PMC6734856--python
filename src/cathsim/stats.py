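"""Evaluation statistics from first principles.

Implements the classical balanced mixed-design (split-plot) repeated-
measures ANOVA: one between-subject factor (group) and one within-subject
factor (repetition).  The group effect is tested against the
subjects-within-groups mean square; the repetition and interaction effects
against the within-subject error mean square.  Also: group summaries,
exponential learning-curve fitting, and noncentral-F power analysis for the
three effects.

The long table is a pandas DataFrame with columns ``subject``, ``group``,
``repetition`` and ``value``; the design must be balanced (every subject has
every repetition exactly once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import MissingGroupError, UnbalancedDesignError

LONG_COLUMNS = ("subject", "group", "repetition", "value")
METRIC_COLUMNS = {"collisions": "n_collisions", "completion_time": "completion_time_s"}


def long_table_from_results(results: pd.DataFrame, metric: str = "collisions") -> pd.DataFrame:
    """Convert a session-results table to the long analysis format."""
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    col = METRIC_COLUMNS[metric]
    out = results.rename(
        columns={"trainee_id": "subject", col: "value"}
    )[["subject", "group", "repetition", "value"]].copy()
    out["value"] = out["value"].astype(float)
    return out


def _to_cells(table: pd.DataFrame) -> tuple[list[str], np.ndarray, list[list[str]]]:
    """Validate balance and reshape to per-group (n_g, m) arrays.

    Returns (group names, stacked (g, n, m) array, subject ids per group).
    Balanced means: all groups have the same number of subjects and every
    subject has every repetition exactly once.
    """
    for c in LONG_COLUMNS:
        if c not in table.columns:
            raise UnbalancedDesignError(f"long table missing column {c!r}")
    groups = sorted(table["group"].unique())
    if len(groups) < 1:
        raise MissingGroupError("table has no groups")
    reps = np.sort(table["repetition"].unique())
    m = len(reps)
    blocks = []
    subjects_per_group = []
    n_ref = None
    for g in groups:
        sub = table[table["group"] == g]
        if sub.empty:
            raise MissingGroupError(f"group {g!r} has no rows")
        pivot = sub.pivot_table(
            index="subject", columns="repetition", values="value", aggfunc="count"
        )
        if pivot.shape[1] != m or pivot.isna().any().any() or (pivot != 1).any().any():
            raise UnbalancedDesignError(
                f"group {g!r}: every subject needs every repetition exactly once"
            )
        wide = sub.pivot(index="subject", columns="repetition", values="value")
        wide = wide.reindex(columns=reps)
        if n_ref is None:
            n_ref = wide.shape[0]
        elif wide.shape[0] != n_ref:
            raise UnbalancedDesignError("groups must have equal subject counts")
        blocks.append(wide.to_numpy(dtype=float))
        subjects_per_group.append(list(wide.index))
    return groups, np.stack(blocks), subjects_per_group


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and sd over all subject x repetition cells."""
    groups, data, _ = _to_cells(table)
    rows = []
    for g, block in zip(groups, data):
        rows.append({"group": g, "mean": float(block.mean()),
                     "sd": float(block.std(ddof=1)) if block.size > 1 else 0.0,
                     "n_cells": int(block.size)})
    return pd.DataFrame(rows)


@dataclass
class EffectRow:
    ss: float
    df: float
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Mixed-design RM-ANOVA decomposition.

    ``effects`` holds group, repetition and group:repetition rows;
    ``errors`` the between-subject (subjects within groups) and
    within-subject error terms.  ``gg_epsilon`` is the Greenhouse-Geisser
    estimate; when the correction is requested the repetition and
    interaction rows use epsilon-scaled degrees of freedom for their p
    values.
    """

    effects: dict[str, EffectRow]
    errors: dict[str, EffectRow]
    ss_total: float
    gg_epsilon: float
    gg_applied: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("group", "subjects_within_groups", "repetition",
                     "group:repetition", "within_error"):
            src = self.effects if name in self.effects else self.errors
            r = src[name]
            rows.append({"effect": name, "ss": r.ss, "df": r.df, "ms": r.ms,
                         "F": r.F, "p": r.p})
        return pd.DataFrame(rows)


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """GG epsilon from the pooled within-group covariance of the m measures."""
    g, n, m = data.shape
    if m < 2:
        return 1.0
    centered = data - data.mean(axis=1, keepdims=True)
    S = np.zeros((m, m))
    for block in centered:
        S += block.T @ block
    S /= max(g * (n - 1), 1)
    # orthonormal contrast transform
    C = np.linalg.qr(np.eye(m) - 1.0 / m)[0][:, : m - 1].T
    V = C @ S @ C.T
    tr = np.trace(V)
    denom = (m - 1) * np.trace(V @ V)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / (m - 1), 1.0))


def rm_anova_cells(data: np.ndarray, gg_correction: bool = False) -> AnovaResult:
    """Mixed-design RM-ANOVA on a (groups, subjects, repetitions) array."""
    data = np.asarray(data, dtype=float)
    g, n, m = data.shape
    if g < 2 or n < 2 or m < 2:
        raise UnbalancedDesignError(
            "need >=2 groups, >=2 subjects per group and >=2 repetitions"
        )
    N = g * n
    grand = data.mean()
    subj_means = data.mean(axis=2)          # (g, n)
    group_means = data.mean(axis=(1, 2))    # (g,)
    rep_means = data.mean(axis=(0, 1))      # (m,)
    cell_means = data.mean(axis=1)          # (g, m)

    ss_total = float(((data - grand) ** 2).sum())
    ss_group = float(n * m * ((group_means - grand) ** 2).sum())
    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_rep = float(N * ((rep_means - grand) ** 2).sum())
    ss_inter = float(
        n * ((cell_means - group_means[:, None] - rep_means[None, :] + grand) ** 2).sum()
    )
    ss_error = ss_total - ss_group - ss_subj_within - ss_rep - ss_inter

    df_group = g - 1
    df_subj = N - g
    df_rep = m - 1
    df_inter = (g - 1) * (m - 1)
    df_error = (N - g) * (m - 1)

    ms_subj = ss_subj_within / df_subj
    ms_error = ss_error / df_error

    eps = greenhouse_geisser_epsilon(data)

    def effect(ss: float, df: int, ms_err: float, df_err: int, scale: float) -> EffectRow:
        ms = ss / df if df > 0 else np.nan
        if df > 0 and ms_err > 0:
            F = ms / ms_err
            p = float(sps.f.sf(F, df * scale, df_err * scale))
        elif df > 0 and ss == 0.0:
            F, p = 0.0, 1.0
        else:  # zero error variance with nonzero effect
            F, p = np.inf, 0.0
        return EffectRow(ss=ss, df=df, ms=ms, F=F, p=p)

    scale = eps if gg_correction else 1.0
    effects = {
        "group": effect(ss_group, df_group, ms_subj, df_subj, 1.0),
        "repetition": effect(ss_rep, df_rep, ms_error, df_error, scale),
        "group:repetition": effect(ss_inter, df_inter, ms_error, df_error, scale),
    }
    errors = {
        "subjects_within_groups": EffectRow(ss_subj_within, df_subj, ms_subj, np.nan, np.nan),
        "within_error": EffectRow(ss_error, df_error, ms_error, np.nan, np.nan),
    }
    return AnovaResult(effects=effects, errors=errors, ss_total=ss_total,
                       gg_epsilon=eps, gg_applied=gg_correction)


def rm_anova(table: pd.DataFrame, gg_correction: bool = False) -> AnovaResult:
    """Mixed-design RM-ANOVA of a balanced long table."""
    _, data, _ = _to_cells(table)
    return rm_anova_cells(data, gg_correction=gg_correction)


def compare_groups(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-sided group-effect test with direction of effect."""
    res = rm_anova(table)
    summary = group_summary(table)
    means = dict(zip(summary["group"], summary["mean"]))
    row = res.effects["group"]
    ordered = sorted(means, key=means.get)
    return {
        "p": row.p,
        "F": row.F,
        "df": (row.df, res.errors["subjects_within_groups"].df),
        "means": means,
        "direction": " < ".join(str(k) for k in ordered),
        "significant": bool(row.p < alpha),
        "alpha": alpha,
    }


def fit_learning_curve(values, repetitions=None) -> dict:
    """Least-squares fit of ``y_k = b + a * exp(-lam * (k - 1))``.

    Profiles the nonlinear rate over a grid (with a bounded refinement);
    for each candidate rate the amplitude/offset pair is solved linearly.
    A flat series yields ``lam = 0`` with ``a = 0``.
    """
    y = np.asarray(values, dtype=float)
    if repetitions is None:
        k = np.arange(1, len(y) + 1, dtype=float)
    else:
        k = np.asarray(repetitions, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 repetitions to fit a learning curve")
    x = k - 1.0

    def solve(lam: float) -> tuple[float, float, float]:
        if lam == 0.0:
            b = float(y.mean())
            return 0.0, b, float(((y - b) ** 2).sum())
        X = np.column_stack([np.exp(-lam * x), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(coef[0]), float(coef[1]), float(resid @ resid)

    grid = np.concatenate([[0.0], np.geomspace(1e-3, 5.0, 60)])
    best_lam, best = 0.0, solve(0.0)
    for lam in grid[1:]:
        cand = solve(lam)
        if cand[2] < best[2] - 1e-12:
            best_lam, best = lam, cand
    if best_lam > 0.0:
        lo = best_lam / 3.0
        hi = min(best_lam * 3.0, 10.0)
        res = optimize.minimize_scalar(
            lambda lam: solve(lam)[2], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best[2]:
            best_lam, best = float(res.x), solve(float(res.x))
    a, b, rss = best
    return {"a": a, "b": b, "lam": best_lam, "rss": rss}


@dataclass
class PowerSpec:
    """Design parameters for RM-ANOVA power analysis (Cohen's f scale)."""

    alpha: float = 0.05
    effect_size_f: float = 0.3
    n_total: int = 16
    groups: int = 2
    measurements: int = 20
    correlation: float = 0.5
    nonsphericity: float = 1.0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_size_f < 0:
            raise ValueError("effect size f must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not 0 < self.nonsphericity <= 1:
            raise ValueError("nonsphericity epsilon must be in (0, 1]")
        if self.n_total < self.groups + 1 or self.groups < 1 or self.measurements < 1:
            raise ValueError("invalid design sizes")


def power_rm_anova(spec: PowerSpec, effect: str = "between") -> float:
    """Noncentral-F power for a mixed-design RM-ANOVA effect.

    Noncentrality (G*Power conventions):
      between       lambda = f^2 N m / (1 + (m - 1) rho)
      within/inter  lambda = f^2 N m eps / (1 - rho)
    with matching (possibly eps-scaled) degrees of freedom.
    """
    spec.validate()
    f2 = spec.effect_size_f**2
    N, g, m = spec.n_total, spec.groups, spec.measurements
    rho, eps = spec.correlation, spec.nonsphericity
    if effect == "between":
        lam = f2 * N * m / (1.0 + (m - 1) * rho)
        df1, df2 = g - 1, N - g
    elif effect == "within":
        lam = f2 * N * m * eps / (1.0 - rho)
        df1, df2 = (m - 1) * eps, (N - g) * (m - 1) * eps
    elif effect == "interaction":
        lam = f2 * N * m * eps / (1.0 - rho)
        df1, df2 = (g - 1) * (m - 1) * eps, (N - g) * (m - 1) * eps
    else:
        raise ValueError(f"unknown effect {effect!r}")
    crit = sps.f.isf(spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(sps.ncf.sf(crit, df1, df2, lam))
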