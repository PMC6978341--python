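"""Percent-of-family profiles and the family variance score (AVS).

A sample's expression over an n-member gene family is converted to percent
of the family total, x_i = 100 * v_i / sum(v). The variance score is the
population variance of that percent vector,

    AVS = sum_i (x_i - mean(x))^2 / n,

in percent^2 units. A perfectly even family profile scores 0; a profile
concentrated in a single member attains the maximum 100^2 (n-1) / n^2
(~498.6 for the 19-member ALDH family). High AVS therefore flags samples
dominated by one isoform; low AVS flags diverse isoform usage. The score
is invariant to overall scaling of the input, so library size cancels.

Cohorts are stratified either at the median score (Fisher-exact style
two-group splits) or at the 25th percentile ("top 75% vs bottom 25%"
survival splits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneFamily, ValidationError

__all__ = [
    "UndefinedProfileError",
    "FamilyProfile",
    "FamilyVarianceResult",
    "GroupAssignment",
    "CohortScores",
    "percent_of_family",
    "avs",
    "avs_max",
    "score_cohort",
    "stratify",
]

logger = logging.getLogger(__name__)


class UndefinedProfileError(ValueError):
    """All family members are zero: percent-of-family is undefined."""


@dataclass
class FamilyProfile:
    """Percent-of-family expression vector for one sample (sums to 100)."""

    sample_id: str
    percents: np.ndarray
    n: int


@dataclass
class FamilyVarianceResult:
    sample_id: str
    avs: float
    n_members: int
    n_missing_in_matrix: int = 0


@dataclass
class GroupAssignment:
    sample_id: str
    group: str  # "high" | "low"
    rule: str  # "median" | "quartile25"
    threshold_value: float


@dataclass
class CohortScores:
    """Per-sample variance scores plus samples whose profile was undefined."""

    results: list[FamilyVarianceResult]
    undefined_samples: list[str] = field(default_factory=list)

    def avs_values(self) -> np.ndarray:
        return np.array([r.avs for r in self.results], dtype=float)


def percent_of_family(sample_values, sample_id: str = "") -> FamilyProfile:
    """Convert raw family-member expression to percent of the family total."""
    v = np.asarray(sample_values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("expected a 1-D vector of family-member values")
    if (v < 0).any():
        raise ValidationError(f"negative expression in sample {sample_id!r}")
    total = v.sum()
    if total == 0:
        raise UndefinedProfileError(
            f"sample {sample_id!r}: family total is zero, percent profile undefined"
        )
    return FamilyProfile(sample_id=sample_id, percents=100.0 * v / total, n=v.size)


def avs(profile: FamilyProfile) -> FamilyVarianceResult:
    """Population variance of the percent profile (percent^2 units)."""
    x = profile.percents
    score = float(np.sum((x - x.mean()) ** 2) / profile.n)
    return FamilyVarianceResult(
        sample_id=profile.sample_id, avs=score, n_members=profile.n
    )


def avs_max(n: int) -> float:
    """Largest attainable score for an n-member family (single nonzero member)."""
    return 100.0**2 * (n - 1) / n**2


def score_cohort(
    matrix: ExpressionMatrix,
    family: GeneFamily,
    missing_policy: str = "error",
) -> CohortScores:
    """Score every sample of a cohort over one gene family.

    ``missing_policy`` controls family members absent from the matrix:
    "error" (default) raises naming the missing symbols; "zero" imputes 0
    and records the count per result. The divisor n is always the full
    family size, including zero-expression members. Samples whose family
    total is zero are excluded from ``results`` and listed in
    ``undefined_samples`` with a logged warning.
    """
    present = [g for g in family.members if g in matrix.data.columns]
    missing = [g for g in family.members if g not in matrix.data.columns]
    if missing:
        if missing_policy == "error":
            raise ValidationError(
                f"matrix is missing family members: {missing} "
                f"(use missing_policy='zero' to impute)"
            )
        if missing_policy != "zero":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sub = matrix.data[present].to_numpy(dtype=float)
    if missing:
        sub = np.hstack([sub, np.zeros((sub.shape[0], len(missing)))])

    out = CohortScores(results=[])
    for sid, row in zip(matrix.sample_ids, sub):
        try:
            profile = percent_of_family(row, sample_id=sid)
        except UndefinedProfileError:
            logger.warning("sample %r has zero family total; excluded from scoring", sid)
            out.undefined_samples.append(sid)
            continue
        res = avs(profile)
        res.n_missing_in_matrix = len(missing)
        out.results.append(res)
    return out


def stratify(
    scores: list[FamilyVarianceResult] | CohortScores,
    rule: str = "median",
) -> list[GroupAssignment]:
    """Assign each scored sample to a "high" or "low" variance group.

    median rule: low iff score <= median (ties go low, deterministically).
    quartile25 rule: low iff score < 25th percentile (linear-interpolation
    percentile), i.e. "high" is the top 75%. All-identical scores give a
    degenerate all-"low" split with a logged warning.
    """
    if isinstance(scores, CohortScores):
        scores = scores.results
    if len(scores) < 2:
        raise ValidationError("stratification needs >= 2 scored samples")
    values = np.array([r.avs for r in scores], dtype=float)
    if np.ptp(values) == 0:
        logger.warning("all scores identical; degenerate stratification (all 'low')")
        return [
            GroupAssignment(r.sample_id, "low", rule, float(values[0])) for r in scores
        ]
    if rule == "median":
        threshold = float(np.median(values))
        low = values <= threshold
    elif rule == "quartile25":
        threshold = float(np.percentile(values, 25))
        low = values < threshold
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return [
        GroupAssignment(r.sample_id, "low" if lo else "high", rule, threshold)
        for r, lo in zip(scores, low)
    ]
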