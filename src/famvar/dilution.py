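"""Limiting-dilution estimation of cancer-initiating-cell (CIC) frequency.

Under the single-hit Poisson model, a graft of d cells forms a tumor with
probability 1 - exp(-d*f), where f is the frequency of cells capable of
initiating a tumor. Given dose-response rows (dose d, n animals tested,
k with tumors), the log-likelihood

    l(f) = sum_rows [ k*log(1 - exp(-d*f)) - (n - k)*d*f ]

is maximized over theta = log(f) by a bracketed root find on the score
equation (the likelihood is unimodal in theta away from the boundaries).
The 95% CI is Wald on log(f) from the observed information — the
convention of classical limiting-dilution calculators — with a
profile-likelihood CI available by flag. With a single dose the MLE has
the closed form f = -ln(1 - k/n)/d, which the numeric fit reproduces.

Degenerate assays are flagged rather than fit: all k = 0 pins the MLE to
the lower boundary (f = 0, one-sided upper confidence bound from the
probability that no graft responds); all k = n pins it to the upper
boundary (capped at f = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .io import ValidationError

__all__ = [
    "DilutionAssay",
    "FrequencyEstimate",
    "ArmComparison",
    "fit_single_hit",
    "compare_arms",
    "depletion_fold",
    "simulate_assay",
]

_Z95 = sps.norm.ppf(0.975)
_THETA_LO = math.log(1e-15)  # f search floor; below any biologically meaningful frequency


@dataclass
class DilutionAssay:
    """Dose-response tumor-incidence rows for one experimental arm."""

    arm: str
    doses: np.ndarray  # cells implanted per graft
    tested: np.ndarray  # animals per dose
    responding: np.ndarray  # animals with palpable tumor

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.tested = np.asarray(self.tested, dtype=int)
        self.responding = np.asarray(self.responding, dtype=int)
        if self.doses.size == 0:
            raise ValidationError("assay has no dose rows")
        if not (self.doses.shape == self.tested.shape == self.responding.shape):
            raise ValidationError("dose, tested and responding columns must align")
        if (self.doses <= 0).any():
            raise ValidationError("doses must be positive")
        if np.unique(self.doses).size != self.doses.size:
            raise ValidationError("doses must be distinct within an arm")
        if (self.tested < 1).any():
            raise ValidationError("each dose needs >= 1 animal")
        if ((self.responding < 0) | (self.responding > self.tested)).any():
            raise ValidationError("responding count must satisfy 0 <= k <= n")


@dataclass
class FrequencyEstimate:
    """Single-hit CIC frequency MLE with 95% CI (per-cell scale)."""

    f: float
    ci_low: float
    ci_high: float
    loglik: float
    se_log_f: float | None = None
    boundary: str | None = None  # None | "lower" | "upper"
    ci_method: str = "wald-log"

    @property
    def reciprocal(self) -> str:
        """The field's ``1/N`` notation (N = cells per CIC)."""
        if self.f <= 0:
            return "1/inf"
        return f"1/{round(1.0 / self.f):d}"


@dataclass
class ArmComparison:
    lr_chi2: float
    p_value: float
    fold: float
    estimate_a: FrequencyEstimate
    estimate_b: FrequencyEstimate
    boundary: bool = False


def _loglik(theta: float, d, n, k) -> float:
    u = d * math.exp(theta)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(-u))
    terms = np.where(k > 0, k * log_p, 0.0)
    return float(np.sum(terms - (n - k) * u))


def _score(theta: float, d, n, k) -> float:
    u = d * math.exp(theta)
    with np.errstate(over="ignore"):
        return float(np.sum(u * (k / np.expm1(u) - (n - k))))


def _observed_info(theta: float, d, n, k) -> float:
    u = d * math.exp(theta)
    with np.errstate(over="ignore"):
        eu = np.expm1(u)
        h = k / eu - (n - k)
        hprime = -k * (1.0 / eu + 1.0 / eu**2)  # stable as eu -> inf
    return float(-np.sum(u * (h + u * hprime)))


def fit_single_hit(
    assay: DilutionAssay, ci: str = "wald", tol: float = 1e-12
) -> FrequencyEstimate:
    """Maximum-likelihood CIC frequency for one arm.

    ``ci`` selects "wald" (on log f; default) or "profile"
    (likelihood-ratio inversion, better behaved near boundaries).
    """
    d, n, k = assay.doses, assay.tested, assay.responding

    if (k == 0).all():
        # P(no graft responds) = exp(-f * sum(n*d)); invert at 0.05
        upper = -math.log(0.05) / float(np.sum(n * d))
        return FrequencyEstimate(
            f=0.0, ci_low=0.0, ci_high=upper, loglik=0.0,
            boundary="lower", ci_method="exact-one-sided",
        )
    if (k == n).all():
        # P(every graft responds) >= 0.05 bounds f from below
        def all_respond(logf: float) -> float:
            return float(np.sum(n * np.log(-np.expm1(-d * np.exp(logf))))) - math.log(0.05)

        lo = math.exp(brentq(all_respond, _THETA_LO, 0.0, xtol=1e-12))
        return FrequencyEstimate(
            f=1.0, ci_low=lo, ci_high=1.0, loglik=_loglik(0.0, d, n, k),
            boundary="upper", ci_method="exact-one-sided",
        )

    score = lambda th: _score(th, d, n, k)
    if score(0.0) >= 0:  # likelihood still rising at f = 1
        return FrequencyEstimate(
            f=1.0, ci_low=float("nan"), ci_high=1.0,
            loglik=_loglik(0.0, d, n, k), boundary="upper",
        )
    theta_hat = brentq(score, _THETA_LO, 0.0, xtol=tol)
    f_hat = math.exp(theta_hat)
    ll_hat = _loglik(theta_hat, d, n, k)
    info = _observed_info(theta_hat, d, n, k)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")

    if ci == "wald":
        lo = math.exp(theta_hat - _Z95 * se)
        hi = min(math.exp(theta_hat + _Z95 * se), 1.0)
    elif ci == "profile":
        drop = sps.chi2.ppf(0.95, df=1) / 2.0
        g = lambda th: _loglik(th, d, n, k) - (ll_hat - drop)
        lo = math.exp(brentq(g, _THETA_LO, theta_hat, xtol=1e-10))
        hi = math.exp(brentq(g, theta_hat, 0.0, xtol=1e-10)) if g(0.0) < 0 else 1.0
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return FrequencyEstimate(
        f=f_hat, ci_low=lo, ci_high=hi, loglik=ll_hat, se_log_f=se,
        ci_method=f"{ci}-log",
    )


def depletion_fold(a: FrequencyEstimate, b: FrequencyEstimate) -> float:
    """Frequency ratio f_a / f_b (e.g. control over knockdown = fold depletion)."""
    if b.f == 0:
        return float("inf") if a.f > 0 else float("nan")
    return a.f / b.f


def compare_arms(a: DilutionAssay, b: DilutionAssay, ci: str = "wald") -> ArmComparison:
    """Likelihood-ratio test of a shared frequency vs per-arm frequencies (df = 1)."""
    est_a = fit_single_hit(a, ci=ci)
    est_b = fit_single_hit(b, ci=ci)
    if est_a.boundary and est_b.boundary:
        raise ValidationError("both arms at a boundary; comparison degenerate")
    d = np.concatenate([a.doses, b.doses])
    n = np.concatenate([a.tested, b.tested])
    k = np.concatenate([a.responding, b.responding])

    # pooled MLE over the concatenated rows (dose repeats across arms are fine here)
    if (k == 0).all():
        ll_pool = 0.0
    elif _score(0.0, d, n, k) >= 0:
        ll_pool = _loglik(0.0, d, n, k)
    else:
        th = brentq(lambda t: _score(t, d, n, k), _THETA_LO, 0.0, xtol=1e-12)
        ll_pool = _loglik(th, d, n, k)

    lr = 2.0 * (est_a.loglik + est_b.loglik - ll_pool)
    lr = max(lr, 0.0)
    p = float(sps.chi2.sf(lr, df=1))
    return ArmComparison(
        lr_chi2=float(lr),
        p_value=p,
        fold=depletion_fold(est_a, est_b),
        estimate_a=est_a,
        estimate_b=est_b,
        boundary=bool(est_a.boundary or est_b.boundary),
    )


def simulate_assay(
    f_true: float,
    doses,
    n_per_dose: int | list[int],
    seed: int | np.random.Generator = 0,
    arm: str = "simulated",
) -> DilutionAssay:
    """Draw k ~ Binomial(n, 1 - exp(-d * f_true)) per dose, reproducibly."""
    if not (0 <= f_true < 1):
        raise ValidationError("f_true must lie in [0, 1)")
    doses = np.asarray(doses, dtype=float)
    n = np.broadcast_to(np.asarray(n_per_dose, dtype=int), doses.shape).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = -np.expm1(-doses * f_true)
    k = rng.binomial(n, p)
    return DilutionAssay(arm=arm, doses=doses, tested=n, responding=k)
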