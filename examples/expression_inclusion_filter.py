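"""The expression inclusion filter on a paired FPKM / read-count matrix.

A gene is kept only if it shows FPKM strictly above 1 AND more than 10
reads in at least 10% of samples, within every condition group.
"""

import numpy as np
import pandas as pd

from armonize import ExpressionMatrix, FilterConfig, expression_filter

rng = np.random.default_rng(0)
genes = [f"g{i}" for i in range(8)]
samples = [f"t{i}" for i in range(10)] + ["c1", "c2"]
groups = pd.Series(["tumor"] * 10 + ["control"] * 2, index=samples)

fpkm_vals = rng.uniform(0, 6, (8, 12))
fpkm_vals[0] = 0.0            # silent gene
fpkm_vals[1] = 1.0            # exactly on the threshold: excluded (strict >)
count_vals = rng.integers(0, 100, (8, 12))
count_vals[0] = 0

fpkm = ExpressionMatrix(pd.DataFrame(fpkm_vals, index=genes, columns=samples), "fpkm", groups)
counts = ExpressionMatrix(pd.DataFrame(count_vals, index=genes, columns=samples),
                          "read_count", groups)

retained, report = expression_filter(fpkm, counts, FilterConfig())
print(f"retained {len(retained)} of {len(genes)} genes: {retained}")
print(report[["tumor_fpkm_pass", "tumor_count_pass", "control_fpkm_pass",
              "control_count_pass", "retained"]].to_string())
print("-> the *_pass columns count samples exceeding each threshold; both "
      "conditions must meet the 10%-of-samples quota.")
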