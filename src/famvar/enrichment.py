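"""Relative mRNA quantification of sorted cell populations by the delta-delta-Ct method.

Fold enrichment of a target gene in the ALDH-high versus ALDH-low sorted
population, each normalized to a reference gene (GAPDH):

    ddCt = (Ct_target,high - Ct_ref,high) - (Ct_target,low - Ct_ref,low)
    fold = 2 ** (-ddCt)

Amplification efficiency is fixed at the ideal doubling of 2 per cycle;
efficiency calibration is out of scope. Replicates are paired by index
(replicate i of the high population against replicate i of the low
population); the per-gene enrichment is the mean of replicate folds with
its s.e.m. The gene with the largest mean fold is the dominant isoform;
exact ties are flagged rather than broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError

__all__ = ["CtRecord", "EnrichmentProfile", "ddct_fold", "build_profile"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference Ct for one sorted population."""

    cell_line: str
    gene: str
    population: str  # "high" | "low"
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.population not in ("high", "low"):
            raise ValidationError(f"population must be 'high' or 'low', got {self.population!r}")
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or not (0 < ct < 45):
                raise ValidationError(f"{name}={ct!r} outside plausible cycle range (0, 45)")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")


@dataclass
class EnrichmentProfile:
    """Per-gene high-vs-low fold enrichment for one cell line."""

    cell_line: str
    genes: list[str]
    mean_fold: dict[str, float]
    sem_fold: dict[str, float]
    dominant_gene: str
    dominant_tie: bool
    enrichment_threshold: float
    n_above_threshold: int
    genes_above_threshold: list[str] = field(default_factory=list)


def ddct_fold(
    ct_t_high: float, ct_r_high: float, ct_t_low: float, ct_r_low: float
) -> float:
    """Fold change (high vs low) for one replicate pair: 2**-ddCt."""
    cts = (ct_t_high, ct_r_high, ct_t_low, ct_r_low)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError(f"non-finite Ct value in {cts}")
    ddct = (ct_t_high - ct_r_high) - (ct_t_low - ct_r_low)
    return float(2.0 ** (-ddct))


def build_profile(
    records: list[CtRecord], enrichment_threshold: float = 5.0
) -> EnrichmentProfile:
    """Summarize replicate Ct records from one cell line into an enrichment profile.

    Requires high/low measurements with matching replicate indices per gene
    (unpaired replicates raise, naming the gene). The default 5-fold
    threshold counts strongly enriched isoforms.
    """
    if not records:
        raise ValidationError("no Ct records supplied")
    lines = {r.cell_line for r in records}
    if len(lines) > 1:
        raise ValidationError(
            f"records span multiple cell lines {sorted(lines)}; profile one at a time"
        )
    cell_line = records[0].cell_line

    by_gene: dict[str, dict[str, dict[int, CtRecord]]] = {}
    for r in records:
        slot = by_gene.setdefault(r.gene, {"high": {}, "low": {}})
        if r.replicate in slot[r.population]:
            raise ValidationError(
                f"duplicate {r.population} replicate {r.replicate} for gene {r.gene!r}"
            )
        slot[r.population][r.replicate] = r

    genes = list(by_gene)
    mean_fold: dict[str, float] = {}
    sem_fold: dict[str, float] = {}
    for gene, slot in by_gene.items():
        if set(slot["high"]) != set(slot["low"]) or not slot["high"]:
            raise ValidationError(
                f"gene {gene!r}: high/low replicate indices do not pair up"
            )
        folds = np.array(
            [
                ddct_fold(
                    slot["high"][i].ct_target,
                    slot["high"][i].ct_reference,
                    slot["low"][i].ct_target,
                    slot["low"][i].ct_reference,
                )
                for i in sorted(slot["high"])
            ]
        )
        mean_fold[gene] = float(folds.mean())
        sem_fold[gene] = (
            float(folds.std(ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else 0.0
        )

    top = max(mean_fold.values())
    top_genes = [g for g in genes if mean_fold[g] == top]
    above = [g for g in genes if mean_fold[g] > enrichment_threshold]
    return EnrichmentProfile(
        cell_line=cell_line,
        genes=genes,
        mean_fold=mean_fold,
        sem_fold=sem_fold,
        dominant_gene=top_genes[0],
        dominant_tie=len(top_genes) > 1,
        enrichment_threshold=enrichment_threshold,
        n_above_threshold=len(above),
        genes_above_threshold=above,
    )
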