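#!/usr/bin/env python
"""Cohort association tests: AVS group vs tumor class, AVS vs stemness.

Three tests on the simulated cohort: Fisher exact on the median-AVS group
by class 2x2 table, Spearman correlation of AVS with the stemness index
(mRNAsi), and a Wilcoxon rank-sum comparison of mRNAsi between classes.
Writes results/associations.tsv.
"""

from pathlib import Path

import pandas as pd

from famvar import io, stats

OUT = Path("results")
scores = pd.read_csv(OUT / "avs_scores.tsv", sep="\t").set_index("sample_id")
clinical = io.read_clinical(OUT / "synthetic" / "clinical.tsv").data
joined = scores.join(clinical, how="inner")

table = stats.crosstab_group_class(joined["group_median"], joined["class_label"])
fisher = stats.fisher_exact_2x2(table)
rho = stats.spearman(joined["avs"], joined["mrnasi"])
labels = sorted(joined["class_label"].unique())
wilcoxon = stats.wilcoxon_rank_sum(
    joined.loc[joined["class_label"] == labels[0], "mrnasi"],
    joined.loc[joined["class_label"] == labels[1], "mrnasi"],
)

results = pd.DataFrame(
    [
        {"test": r.name, "statistic": r.statistic, "estimate": r.estimate,
         "p_value": r.p_value, "n": r.n, "method": r.method}
        for r in (fisher, rho, wilcoxon)
    ]
)
results.to_csv(OUT / "associations.tsv", sep="\t", index=False)

print(f"high/low AVS x class table: a={table.a} b={table.b} c={table.c} d={table.d}")
print(f"Fisher exact: p = {fisher.p_value:.3g}")
print(f"Spearman AVS~mRNAsi: rho = {rho.statistic:.3f}, p = {rho.p_value:.3g} (n = {rho.n})")
print(f"Wilcoxon mRNAsi {labels[0]} vs {labels[1]}: p = {wilcoxon.p_value:.3g}")
print(f"wrote {OUT / 'associations.tsv'}")
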