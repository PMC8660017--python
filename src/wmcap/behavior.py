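"""Behavioral performance analysis for the change-localization task.

Per-session performance by ipsilateral load, the ipsi-by-contra performance
matrix, Cowan's capacity estimate K = n * p, a Friedman test of the load
effect across sessions, and a linear model of session performance on ipsi
load, contra load and their interaction, with a reduced-model
log-likelihood comparison for the contra main effect.

Ipsilateral here always means the hemifield in which the color change
occurred; aborted and no-response trials are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import DomainError, as_trial_list

COMPLETED = ("correct", "error")


def _completed_frame(trials) -> pd.DataFrame:
    rows = []
    for t in as_trial_list(trials):
        if t.outcome not in COMPLETED:
            continue
        rows.append(
            (t.session_id, t.ipsi_load(), t.contra_load(), t.total_load,
             1.0 if t.outcome == "correct" else 0.0)
        )
    return pd.DataFrame(
        rows, columns=["session_id", "ipsi", "contra", "total", "correct"]
    )


def performance_by_load(trials) -> pd.DataFrame:
    """Proportion correct per (session, ipsilateral load).

    Returns a session x load table (loads 1-3 as columns); cells with no
    completed trials are NaN, never zero.  Column-wise medians over
    sessions are available via ``.median()``.
    """
    df = _completed_frame(trials)
    if df.empty:
        return pd.DataFrame(columns=[1, 2, 3], dtype=float)
    table = (
        df.groupby(["session_id", "ipsi"])["correct"].mean().unstack("ipsi")
    )
    return table.reindex(columns=[1, 2, 3])


def performance_matrix(trials) -> pd.DataFrame:
    """Mean proportion correct per (ipsi load, contra load) cell.

    The (3,3) cell is absent by design (six items exceed the task's
    five-item maximum) and stays NaN.
    """
    df = _completed_frame(trials)
    out = pd.DataFrame(np.nan, index=[1, 2, 3], columns=[1, 2, 3])
    if df.empty:
        return out
    means = df.groupby(["ipsi", "contra"])["correct"].mean()
    for (i, c), v in means.items():
        out.loc[i, c] = v
    return out


@dataclass
class CapacityEstimate:
    """Cowan's K for one array size: K = n * p."""

    n: int
    p: float
    K: float


def cowan_k(n: int, p: float) -> CapacityEstimate:
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise DomainError("p must lie in [0, 1]")
    return CapacityEstimate(n=n, p=float(p), K=float(n * p))


def capacity_by_total_load(trials) -> pd.DataFrame:
    """K per total array size (2-5 items), per session and overall mean/SEM."""
    df = _completed_frame(trials)
    rows = []
    for (sess, n), sub in df.groupby(["session_id", "total"]):
        if n < 2:
            continue
        est = cowan_k(int(n), sub["correct"].mean())
        rows.append((sess, est.n, est.p, est.K))
    per = pd.DataFrame(rows, columns=["session_id", "n", "p", "K"])
    summary = per.groupby("n")["K"].agg(["mean", "sem", "count"])
    return per, summary


def friedman_load_test(perf_table: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square over sessions (blocks) x loads (treatments).

    ``perf_table`` is the output of :func:`performance_by_load`.  Sessions
    with any missing load cell must be removed first; their presence raises.
    """
    if perf_table.isna().any().any():
        raise DomainError(
            "performance table has missing (session, load) cells; remove "
            "incomplete sessions (listwise) before the Friedman test"
        )
    if len(perf_table) < 2:
        raise DomainError("need at least two complete sessions")
    arr = perf_table.to_numpy(dtype=float)
    if np.all(arr.max(axis=1) == arr.min(axis=1)):
        # every session fully tied: rank variance is zero by construction
        return 0.0, 1.0
    cols = [perf_table[c].to_numpy(dtype=float) for c in perf_table.columns]
    chi2, p = stats.friedmanchisquare(*cols)
    return float(chi2), float(p)


@dataclass
class GlmFit:
    """Linear model of session performance on load predictors."""

    params: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    df_resid: int
    r2_adj: float
    f: float
    f_p: float
    llf: float


def _fit(y: np.ndarray, X: pd.DataFrame) -> GlmFit:
    model = sm.OLS(y, sm.add_constant(X))
    res = model.fit()
    return GlmFit(
        params=dict(res.params),
        tvalues=dict(res.tvalues),
        pvalues=dict(res.pvalues),
        df_resid=int(res.df_resid),
        r2_adj=float(res.rsquared_adj),
        f=float(res.fvalue),
        f_p=float(res.f_pvalue),
        llf=float(res.llf),
    )


def fit_load_glm(trials, center: bool = False
                 ) -> tuple[GlmFit, GlmFit, float]:
    """Session-level linear model of performance on ipsi and contra load.

    Aggregates completed trials to one row per (session, ipsi, contra) cell,
    fits performance ~ ipsi + contra + ipsi:contra by ordinary least squares
    (Gaussian error, identity link), refits without the contra main effect,
    and returns (full fit, reduced fit, |delta log-likelihood|).
    """
    df = _completed_frame(trials)
    rows = (
        df.groupby(["session_id", "ipsi", "contra"])["correct"]
        .mean()
        .reset_index()
    )
    if len(rows) < 10:
        raise DomainError("need at least 10 session-level rows")
    ipsi = rows["ipsi"].to_numpy(dtype=float)
    contra = rows["contra"].to_numpy(dtype=float)
    if center:
        ipsi = ipsi - ipsi.mean()
        contra = contra - contra.mean()
    X_full = pd.DataFrame(
        {"ipsi": ipsi, "contra": contra, "ipsi_x_contra": ipsi * contra}
    )
    for col in X_full.columns:
        others = X_full.drop(columns=col)
        resid = X_full[col] - sm.OLS(
            X_full[col], sm.add_constant(others)
        ).fit().fittedvalues
        if np.allclose(resid, 0):
            raise DomainError(f"design is rank deficient: column {col!r} is "
                              "collinear with the others")
    y = rows["correct"].to_numpy(dtype=float)
    full = _fit(y, X_full)
    reduced = _fit(y, X_full.drop(columns="contra"))
    return full, reduced, abs(full.llf - reduced.llf)
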