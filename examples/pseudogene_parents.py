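"""Pseudogene -> parental-gene association and correlation patterns.

Generates an alignment-hit table with known true parents plus decoys,
assigns each pseudogene its best-hit parent (minimum e-value), tallies
parent multiplicities, and estimates the pseudogene-parent log2FC slope on
simulated pairs with a known generating slope.
"""

import numpy as np
import pandas as pd

from armonize import best_hit, pair_correlation, unique_parents
from armonize.simulate import gen_hit_table

hits, truth = gen_hit_table(n_pseudogenes=60, n_parents=25, n_decoys=5, seed=3)
assoc = best_hit(hits)
recovered = sum(a.parent_gene_id == truth[a.pseudogene_id] for a in assoc)
parents, multiplicity = unique_parents(assoc)
low_sim = sum(not a.high_similarity for a in assoc)

print(f"associated {len(assoc)} pseudogenes; {recovered} match the true parent")
print(f"{len(parents)} unique parents; "
      f"{sum(1 for c in multiplicity.values() if c > 1)} collect multiple pseudogenes")
print(f"{low_sim} associations fall below the 90% identity flag")

rng = np.random.default_rng(3)
pseudo = rng.normal(0, 2, 150)
pairs = pd.DataFrame({
    "pseudo_lfc": pseudo,
    "parent_lfc": 0.3 * pseudo + rng.normal(0, 1, 150),
    "expression_level": rng.uniform(0, 10, 150),
})
print("\nper-stratum correlation (true generating slope 0.3):")
print(pair_correlation(pairs, strata=3).to_string(index=False))
print("-> weak but recurring slopes across expression strata are the expected "
      "pseudogene-parent pattern.")
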