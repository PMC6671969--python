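"""Gene-set enrichment and extreme-phenotype gene properties.

With synthetic annotations in which high-constraint scores track the
genes with the strongest phenotypes, compares the top and bottom 10% of
genes by maximum absolute z-score (right-tailed Mann-Whitney), tests a
gene set for overrepresentation among the top genes (right-tailed
Fisher) and regresses phenotype strength on a constraint metric.
"""

import numpy as np
import pandas as pd

from napmap import (
    constraint_regression,
    fisher_enrichment,
    mwu_property_test,
    select_extreme_deciles,
    simulate_gene_annotations,
)

rng = np.random.default_rng(8)
genes = [f"G{i:03d}" for i in range(400)]
calls = pd.DataFrame({"gene": genes,
                      "max_abs_z": np.abs(rng.normal(size=400))})
top, bottom = select_extreme_deciles(calls, frac=0.10)
print(f"{len(top)} genes per tail from {len(genes)}")

ann = simulate_gene_annotations(genes, top, assoc_strength=1.5, seed=9)
ann = ann.set_index("gene_id")
u, p = mwu_property_test(ann.loc[sorted(top), "pli"],
                         ann.loc[sorted(bottom), "pli"], tail="right")
print(f"pLI, top vs bottom decile: U = {u:.0f}, right-tailed p = {p:.2e}")

panel = set(rng.choice(sorted(top), 20, replace=False)) | \
    set(rng.choice(genes, 20, replace=False))
enr = fisher_enrichment(top, panel, set(genes))
print(f"gene-set overlap {enr.a}/{len(top)}: OR = {enr.odds_ratio:.2f}, "
      f"p = {enr.p_right:.2e}")

slope, p_reg = constraint_regression(calls, ann.reset_index(), "pli")
print(f"max|z| ~ pLI regression: slope = {slope:.3f}, p = {p_reg:.3g}")
# a positive slope says stronger brain phenotypes go with higher constraint
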