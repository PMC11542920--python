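"""Group statistics: t / Mann-Whitney tests with Holm correction.

Builds a long-format table of per-region effect sizes for two treatment
groups and runs the family of comparisons the pipeline uses, printing the
adjusted p values and significance stars.
"""
import numpy as np
import pandas as pd

from aquaflux.stats import group_compare, mann_whitney_u

rng = np.random.default_rng(0)
rows = []
for region, shift in [("cortex", 4.0), ("striatum", 5.0), ("hippocampus", 0.5)]:
    for group, delta in [("saline", 0.0), ("TGN-020", shift)]:
        for v in rng.normal(delta, 2.0, 7):          # 7 animals per group
            rows.append({"family": region, "group": group, "value": v})

table = group_compare(pd.DataFrame(rows), test="mannwhitney")
print(table[["family", "n1", "n2", "statistic", "pvalue", "p_adjusted", "stars"]]
      .to_string(index=False))

r = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
print(f"\nfully separated 3v3 groups: U = {r.statistic:.0f}, exact p = {r.pvalue:.3f}")
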