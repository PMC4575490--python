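"""qPCR delta-delta Ct fold-changes and platform concordance calls.

Builds a small Ct table (housekeeping-normalized), computes fold-changes,
and classifies a platform's fold-changes against the qPCR reference.
"""

import pandas as pd

from titrabench.concordance import (
    ConcordanceCall,
    CtTable,
    concordance_rate,
    delta_delta_ct,
    qc_ct,
    signed_fold_change,
)

rows = []
# gene UP shifts -2 cycles in BMO (4-fold up); DOWN shifts +1 (2-fold down)
for gene, shift in (("GUSB", 0.0), ("UP", -2.0), ("DOWN", 1.0), ("FLAT", 0.0)):
    for sample, s in (("AGO", 0.0), ("BMO", shift)):
        for rep in (1, 2, 3):
            rows.append({"gene_id": gene, "sample": sample,
                         "replicate": rep, "ct": 26.0 + s + 0.05 * rep})
table = qc_ct(pd.DataFrame(rows), housekeeping="GUSB")
fold = delta_delta_ct(table, reference_sample="AGO")
print("qPCR BMO/AGO fold-changes (2^-ddCt):")
print(fold["BMO"].round(2).to_string())

# platform fold-changes to compare (signed: negative = down-regulated)
platform_fc = {"UP": 1.7, "DOWN": -1.9, "FLAT": 1.1}
calls = [
    ConcordanceCall(g, signed_fold_change(float(fold.loc[g, "BMO"])), y)
    for g, y in platform_fc.items()
]
for c in calls:
    print(f"{c.gene_id}: qPCR {c.x:+.2f} vs platform {c.y:+.2f} -> {c.verdict}")
print(f"concordance rate: {concordance_rate(calls):.0f}%")

# "compressed" marks genes whose platform fold-change is at most half the
# qPCR magnitude in the same direction; the rate counts concordant +
# overestimate calls.
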