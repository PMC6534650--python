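"""Rank the genes inside a significant set by their contribution to the
dispersion statistic (delta SSMD).

One gene of the planted set gets a much larger variance inflation than the
rest; the leave-one-gene-out decomposition should place it first.
"""

import numpy as np

from aberex import (
    CohortBundle, CohortConfig, delta_ssmd, generate_cohort,
    split_by_disorder,
)

cfg = CohortConfig(n_genes=400, n_aut=30, n_scz=8, n_bpd=8,
                   n_controls_batch1=40, n_controls_batch2=10,
                   n_modules=0, sets_per_disorder=1, set_size=8,
                   tau=2.0, n_hidden=0, batch_sd=0.0)
expr, samples, truth = generate_cohort(cfg, seed=3)
ps = truth.sets_for("AUT")[0]

# inflate one member gene far beyond the rest
star = ps.genes[0]
cases = samples.index[samples["diagnosis"] == "AUT"]
expr.loc[star, cases] += np.random.default_rng(0).normal(
    0, 4.0, size=len(cases))

bundle = split_by_disorder(CohortBundle(expr, samples))["AUT"]
table = delta_ssmd(list(ps.genes), bundle.controls(), bundle.cases("AUT"),
                   seed=5)
print(f"set {ps.name}: SSMD = {table.attrs['ssmd']:.1f}")
print(table.to_string(index=False,
                      formatters={"delta_ssmd": "{:.1f}".format,
                                  "pct_of_ssmd": "{:.1f}%".format}))
print(f"\nexpected top contributor: {star}")
# delta SSMD is the drop in the statistic when the gene is removed and the
# robust fit is redone; the percentage column is 100 * delta / SSMD.  The
# values need not sum to 100%: removing a gene changes the whole covariance
# model, and a redundant gene can even have a negative contribution.
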