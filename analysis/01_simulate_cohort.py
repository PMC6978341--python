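#!/usr/bin/env python
"""Generate the synthetic two-class tumor cohort used by the downstream analyses.

Writes matrix.tsv (400 samples x 19 ALDH isoforms, RSEM-like), clinical.tsv
(class label, stemness index, survival) and truth.tsv (generator ground
truth) under results/synthetic/.
"""

from pathlib import Path

from famvar import io
from famvar.simulate import SyntheticConfig, generate_cohort

OUT = Path("results/synthetic")
SEED = 42

config = SyntheticConfig(seed=SEED)
cohort = generate_cohort(config)

OUT.mkdir(parents=True, exist_ok=True)
io.write_expression_matrix(cohort.matrix, OUT / "matrix.tsv")
io.write_clinical(cohort.clinical, OUT / "clinical.tsv")
cohort.truth.to_csv(OUT / "truth.tsv", sep="\t", float_format="%.17g")

counts = cohort.clinical.data["class_label"].value_counts()
print(f"cohort of {len(cohort.clinical)} samples (seed {SEED}):")
for label, n in counts.items():
    print(f"  {label}: {n}")
print(f"wrote matrix/clinical/truth TSVs to {OUT}/")
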