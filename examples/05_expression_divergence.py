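"""Quantify expression divergence between species and between hybrid alleles.

Simulates negative-binomial counts for two species and a hybrid allele
table under cis-maintained regulation, recovers per-gene log2 fold changes
from TPM, filters the hybrid table, and normalises hybrid-allele fold
changes to the species fold changes (a value of ~1 means the species
difference is maintained in the hybrid).
"""

import numpy as np
import pandas as pd
from scipy import stats

from promevol import (
    hybrid_allele_filter,
    hybrid_vs_nonhybrid_ratio,
    log2fc,
    log2fc_table,
    tpm,
)
from promevol.simulate import ExpressionConfig, simulate_expression

rng = np.random.default_rng(23)
cfg = ExpressionConfig(n_genes=200, hybrid_scenario="cis_maintained")
counts_a, counts_b, lengths, hybrid, truth = simulate_expression(cfg, rng)

species_lfc = log2fc_table(tpm(counts_a, lengths), tpm(counts_b, lengths))
rho = stats.spearmanr(species_lfc, truth.loc[species_lfc.index, "log2fc_ab"]).statistic
print(f"species log2FC recovered from TPM: Spearman rho vs truth = {rho:.3f}")

filtered = hybrid_allele_filter(hybrid)  # drops X-linked and <4-sample genes
print(f"hybrid table: {hybrid['gene'].nunique()} genes -> "
      f"{filtered['gene'].nunique()} after X/low-detection filters")

cols = [c for c in filtered.columns if c.startswith("hyb_")]
piv = filtered.pivot(index="gene", columns="allele", values=cols)
rows = []
for g in piv.index:
    allele_lfc = log2fc(piv.loc[g].xs("A", level="allele").to_numpy(),
                        piv.loc[g].xs("B", level="allele").to_numpy())
    s_lfc = species_lfc[g]
    if abs(s_lfc) >= 1:
        rows.append({"gene": g, "species_log2fc": s_lfc, "allele_log2fc": allele_lfc,
                     "hybrid_vs_nonhybrid": hybrid_vs_nonhybrid_ratio(s_lfc, allele_lfc)})
table = pd.DataFrame(rows).head(8)
print(table.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
print("# ratios near 1: species-specific expression maintained between the "
      "hybrid alleles (cis regulation).")
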