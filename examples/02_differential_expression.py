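"""Detect a nuclear-restricted cold response in simulated count tables.

Injects a 4-fold upregulation into 100 of 1,000 genes in the nuclear fraction
only, runs the NB Wald test per compartment and classifies genes by their
cross-compartment significance pattern -- the signature of transcripts that
accumulate in the nucleus because export, not synthesis, changed.
"""
import numpy as np
import pandas as pd

from coldclock import expression

rng = np.random.default_rng(1)


def nb(mean, size):
    return rng.poisson(rng.gamma(10.0, np.broadcast_to(mean, size) / 10.0))


n_genes, n_injected = 1000, 100
means = rng.uniform(20, 2000, n_genes)
eff = np.ones(n_genes)
eff[:n_injected] = 4.0

idx = [f"g{i}" for i in range(n_genes)]
cols = [f"s{j}" for j in range(12)]
warm, cold = cols[:6], cols[6:]

nuclear = pd.DataFrame(
    np.hstack([nb(means[:, None], (n_genes, 6)), nb((means * eff)[:, None], (n_genes, 6))]),
    index=idx, columns=cols,
)
cytoplasmic = pd.DataFrame(nb(means[:, None], (n_genes, 12)), index=idx, columns=cols)

de_nuc = expression.nb_wald_de(nuclear, warm, cold)
de_cyt = expression.nb_wald_de(cytoplasmic, warm, cold)
table, summary = expression.nk_scatter_classes(de_nuc, de_cyt, base_mean_min=30)

print(f"genes passing the base-mean filter: {summary['n_genes']}")
print(f"class counts: {summary['counts']}")
print(f"nuclear log2FC vs cytoplasmic log2FC Pearson r: {summary['pearson_r']:.3f}")
hit = (table.loc[table.index.intersection(idx[:n_injected]), "class"]
       == "nucleus_only").mean()
print(f"injected genes recovered as nucleus-only: {100 * hit:.0f}%  "
      "(the nuclear-restricted pattern)")
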