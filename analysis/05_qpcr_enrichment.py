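#!/usr/bin/env python
"""Delta-delta-Ct enrichment profile of a sorted ALDH-high vs ALDH-low population.

Emulates the qPCR readout of a cell line whose ALDH-high fraction is
dominated by one isoform: a synthetic Ct table (ALDH1A3 enriched 12-fold,
triplicates, 0.2-cycle noise) is profiled with the 2^-ddCt method.
Writes results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from famvar.enrichment import build_profile
from famvar.simulate import generate_ct_table

OUT = Path("results")
records = generate_ct_table(
    "ALDH1A3", fold=12.0, n_replicates=3, noise_sd=0.2, seed=42,
    cell_line="synthetic-dominant",
)
profile = build_profile(records, enrichment_threshold=5.0)

table = pd.DataFrame(
    {
        "gene": profile.genes,
        "mean_fold": [profile.mean_fold[g] for g in profile.genes],
        "sem_fold": [profile.sem_fold[g] for g in profile.genes],
        "above_5fold": [g in profile.genes_above_threshold for g in profile.genes],
    }
).sort_values("mean_fold", ascending=False)
table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

dom = profile.dominant_gene
print(f"dominant isoform: {dom} "
      f"({profile.mean_fold[dom]:.1f} +/- {profile.sem_fold[dom]:.1f}-fold, "
      f"{'tie' if profile.dominant_tie else 'unique'})")
print(f"{profile.n_above_threshold} isoform(s) enriched > {profile.enrichment_threshold:g}-fold")
print(f"wrote {OUT / 'enrichment.tsv'}")
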