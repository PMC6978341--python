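"""Cohort-level association tests: Fisher exact, Spearman, Wilcoxon rank-sum.

Thin, contract-checked wrappers over scipy.stats with the conventions made
explicit:

- Fisher exact (2x2) is two-sided by the probability-mass rule (sum of
  hypergeometric probabilities of tables, at fixed margins, no more likely
  than the observed one); the conditional odds ratio a*d/(b*c) is reported,
  with zero/infinite estimates flagged. A zero margin yields p = 1 with a
  degenerate flag.
- Spearman uses average ranks for ties and the t-approximation with n-2 df
  for p; an exact permutation p is available for small n. Missing values
  are removed pairwise.
- Wilcoxon rank-sum (Mann-Whitney) uses the exact null when the combined n
  is <= 12 with no ties, otherwise the normal approximation with tie and
  continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "fisher_exact_2x2",
    "spearman",
    "wilcoxon_rank_sum",
    "crosstab_group_class",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = variance-score group and columns = tumor class."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or int(x) != x for x in cells):
            raise ValidationError(f"counts must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValidationError("contingency table total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class AssociationResult:
    name: str
    statistic: float
    p_value: float
    n: int
    estimate: float | None = None
    degenerate: bool = False
    method: str = ""


def crosstab_group_class(groups, labels) -> ContingencyTable2x2:
    """Tabulate high/low group against a binary class label."""
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    if groups.shape != labels.shape:
        raise ValidationError("group and label vectors must align")
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 class labels, got {classes}")
    a = int(np.sum((groups == "high") & (labels == classes[0])))
    b = int(np.sum((groups == "high") & (labels == classes[1])))
    c = int(np.sum((groups == "low") & (labels == classes[0])))
    d = int(np.sum((groups == "low") & (labels == classes[1])))
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_2x2(table: ContingencyTable2x2) -> AssociationResult:
    arr = table.as_array()
    degenerate = bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())
    if degenerate:
        return AssociationResult(
            name="fisher_exact", statistic=1.0, p_value=1.0,
            n=int(arr.sum()), estimate=None, degenerate=True, method="two-sided",
        )
    res = sps.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return AssociationResult(
        name="fisher_exact", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=int(arr.sum()), estimate=odds,
        degenerate=not np.isfinite(odds), method="two-sided",
    )


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact: bool = False) -> AssociationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    ``exact=True`` (n <= 10 only) replaces the t-approximation p-value with
    a full permutation enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for a constant vector")
    if exact:
        if n > 10:
            raise ValidationError("exact permutation p limited to n <= 10")
        rho_obs = _spearman_rho(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        count = 0
        total = 0
        for perm in permutations(ry):
            rho = np.corrcoef(rx, perm)[0, 1]
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return AssociationResult(
            name="spearman", statistic=rho_obs, p_value=count / total,
            n=n, estimate=rho_obs, method="exact-permutation",
        )
    rho, p = sps.spearmanr(x, y)
    return AssociationResult(
        name="spearman", statistic=float(rho), p_value=float(p),
        n=n, estimate=float(rho), method="t-approximation",
    )


def wilcoxon_rank_sum(group1, group2) -> AssociationResult:
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and (g1.size + g2.size) <= 12
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        g1, g2, alternative="two-sided", method=method, use_continuity=True
    )
    return AssociationResult(
        name="wilcoxon_rank_sum", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)), n=int(g1.size + g2.size), method=method,
    )
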