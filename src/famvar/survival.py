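"""Five-year survival analysis: Kaplan-Meier, log-rank, univariate Cox.

Follow-up is administratively truncated at a horizon (default 60 months)
before estimation: subjects with later times are censored at the horizon.
Kaplan-Meier curves and Cox fits are delegated to lifelines; the two-group
log-rank test is computed directly from the per-event-time hypergeometric
tables so per-group observed and expected event counts can be reported.

Cox models are univariate with Efron tie handling (the lifelines default,
preferred over Breslow for month-resolution data with heavy ties). The
family scan fits one model per family member per tumor class on a
configurable covariate scale, defaulting to log2(expression + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .io import ClinicalTable, ExpressionMatrix, GeneFamily, ValidationError

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "truncate_followup",
    "km_estimate",
    "logrank",
    "cox_univariate",
    "cox_family_scan",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 60.0


@dataclass
class SurvivalCurve:
    times: np.ndarray  # event-time grid (months), starts at 0
    survival: np.ndarray  # S(t) on the grid, starts at 1
    at_risk: np.ndarray
    censor_times: np.ndarray
    horizon: float | None = None


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events
    df: int = 1
    degenerate: bool = False


@dataclass
class CoxResult:
    name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    beta: float
    se: float
    covariate_transform: str = "identity"


def truncate_followup(times, events, horizon: float = DEFAULT_HORIZON_MONTHS):
    """Censor all follow-up beyond the horizon (months)."""
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    t = np.asarray(times, dtype=float).copy()
    e = np.asarray(events, dtype=int).copy()
    late = t > horizon
    t[late] = horizon
    e[late] = 0
    return t, e


def km_estimate(times, events, horizon: float | None = None) -> SurvivalCurve:
    """Product-limit survival estimate (right-continuous; censored stay at risk through t)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("need >= 1 subject")
    if horizon is not None:
        t, e = truncate_followup(t, e, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
        horizon=horizon,
    )


def logrank(times, events, group) -> LogRankResult:
    """Two-group log-rank test, (O1 - E1)^2 / V with hypergeometric variance."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels.size}")
    in1 = g == levels[0]

    o1 = e1 = v = 0.0
    for tk in np.unique(t[e == 1]):
        at_risk = t >= tk
        n_t = at_risk.sum()
        n1_t = (at_risk & in1).sum()
        d_t = ((t == tk) & (e == 1)).sum()
        d1_t = ((t == tk) & (e == 1) & in1).sum()
        o1 += d1_t
        e1 += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)

    total_events = float(e.sum())
    observed = np.array([o1, total_events - o1])
    expected = np.array([e1, total_events - e1])
    if total_events == 0 or v == 0:
        return LogRankResult(
            statistic=0.0, p_value=1.0, observed=observed, expected=expected,
            degenerate=True,
        )
    chi2 = (o1 - e1) ** 2 / v
    return LogRankResult(
        statistic=float(chi2),
        p_value=float(sps.chi2.sf(chi2, df=1)),
        observed=observed,
        expected=expected,
    )


def cox_univariate(
    covariate,
    times,
    events,
    name: str = "x",
    ties: str = "efron",
    covariate_transform: str = "identity",
) -> CoxResult:
    """Univariate Cox proportional-hazards fit.

    Maximizes the partial likelihood (Efron or Breslow tie handling) by
    Newton iteration; reports HR = exp(beta) with 95% Wald CI from the
    observed information. Perfect separation surfaces as a convergence
    error; a constant covariate is rejected up front.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if x.size != t.size or x.size != e.size:
        raise ValidationError("covariate, times and events must align")
    if x.size < 2 or e.sum() < 1:
        raise ValidationError("need >= 2 subjects with >= 1 event")
    if np.ptp(x) == 0:
        raise ValidationError("constant covariate: hazard ratio unidentifiable")

    df = pd.DataFrame({"T": t, "E": e, name: x})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df, duration_col="T", event_col="E",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Cox fit for {name!r} failed to converge "
                f"(monotone likelihood / perfect separation?): {err}"
            ) from err
    beta = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    ci = cph.confidence_intervals_.loc[name]
    return CoxResult(
        name=name,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc[name, "p"]),
        n=int(x.size),
        events=int(e.sum()),
        beta=beta,
        se=se,
        covariate_transform=covariate_transform,
    )


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == "identity":
        return values
    if how == "log2p1":
        return np.log2(values + 1.0)
    raise ValueError(f"unknown covariate transform {how!r}")


def cox_family_scan(
    matrix: ExpressionMatrix,
    family: GeneFamily,
    clinical: ClinicalTable,
    covariate_transform: str = "log2p1",
    horizon: float | None = DEFAULT_HORIZON_MONTHS,
    missing_policy: str = "error",
    min_events: int = 2,
) -> pd.DataFrame:
    """Per-member univariate Cox fits, run separately within each tumor class.

    Returns a table with one row per (class_label, gene): HR, 95% CI, p,
    n, events and the covariate scale used. Class cohorts with fewer than
    ``min_events`` events, and genes whose fit is degenerate in a cohort,
    are skipped with a warning.
    """
    shared = [s for s in matrix.sample_ids if s in clinical.data.index]
    if not shared:
        raise ValidationError("matrix and clinical table share no sample ids")
    missing = [g for g in family.members if g not in matrix.data.columns]
    if missing and missing_policy == "error":
        raise ValidationError(f"matrix is missing family members: {missing}")

    clin = clinical.data.loc[shared]
    rows = []
    for label, sub in clin.groupby("class_label", sort=True):
        t = sub["time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=int)
        if horizon is not None:
            t, e = truncate_followup(t, e, horizon)
        if int(e.sum()) < min_events:
            logger.warning(
                "class %r: only %d events (< %d); all members skipped",
                label, int(e.sum()), min_events,
            )
            continue
        for gene in family.members:
            if gene not in matrix.data.columns:
                logger.warning("class %r: gene %s absent from matrix; skipped", label, gene)
                continue
            x = _transform(
                matrix.data.loc[sub.index, gene].to_numpy(dtype=float),
                covariate_transform,
            )
            try:
                res = cox_univariate(
                    x, t, e, name=gene, covariate_transform=covariate_transform
                )
            except (ValidationError, ConvergenceError) as err:
                logger.warning("class %r: gene %s skipped (%s)", label, gene, err)
                continue
            rows.append(
                {
                    "class_label": label, "gene": gene, "hr": res.hr,
                    "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                    "n": res.n, "events": res.events,
                    "covariate_transform": covariate_transform,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "class_label", "gene", "hr", "ci_low", "ci_high", "p", "n",
            "events", "covariate_transform",
        ],
    )
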