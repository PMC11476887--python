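"""Simulate a 4-vs-4 count matrix with planted fold changes and call DE.

Prints how many of the planted differentially expressed genes the
NB Wald test recovers at adjusted p < 0.05, and how many calls are
false positives.
"""

import pandas as pd

from exmr import diffexpr, synthio

cfg = synthio.SimConfig(seed=1, n_genes=1000, de_fraction=0.1,
                        lfc_magnitude=1.5)
counts, truth = synthio.simulate_counts(cfg, "gene")
groups = pd.Series({s: s.split("_")[0] for s in counts.columns})

results = diffexpr.nb_wald_test(counts, groups)
called = set(results.loc[results["padj"] < 0.05, "feature"])
planted = set(truth)

up, down, total = diffexpr.sign_split(results)
print(f"{total} DE calls ({up} up, {down} down) among {len(results)} genes")
print(f"sensitivity: {len(called & planted)}/{len(planted)} planted genes "
      f"recovered; {len(called - planted)} false positives")
print("Top calls (padj-sorted):")
print(results.head(5).to_string(index=False))
# A sensitivity near 1 with few false positives means the planted
# 2^1.5-fold group differences dominate the NB sampling noise at 4 vs 4.
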