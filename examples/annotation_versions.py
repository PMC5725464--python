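"""Annotation bookkeeping: release comparison and biotype decomposition.

Reproduces the printed release-survival arithmetic (62,893 genes in the
older annotation, 51,858 shared with the newer one) and decomposes a gene
selection by biotype with the parental-gene roll-up.
"""

from armonize import BiotypeCatalog, biotype_decompose, compare_annotation_versions

old = {f"ENSG{i:011d}" for i in range(62893)}
shared = {f"ENSG{i:011d}" for i in range(51858)}
new = shared | {f"NOVEL{i:07d}" for i in range(58051 - 51858)}
res = compare_annotation_versions(old, new)
print(f"shared genes: {res.shared}")
print(f"{res.pct_shared}% of the older release survives; {res.pct_absent}% is gone")

catalog = BiotypeCatalog(
    biotypes={
        "gA": "protein_coding", "gB": "protein_coding", "gC": "pseudogene",
        "gD": "lincRNA", "gE": "antisense",
    },
    families={"gA": {"oncogene", "kinase"}, "gB": {"tumor_suppressor"}},
    parental={"gB"},
)
b = biotype_decompose(["gA", "gB", "gC", "gD", "gX"], catalog)
print("\nbiotype counts:", b.biotype_counts)
print("parental roll-up (overlaps protein_coding):", b.parental_rollup)
print("strict partition:", b.strict_counts)
print("-> every selected gene counts once per column; unknown ids land in "
      "'unclassified'.")
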