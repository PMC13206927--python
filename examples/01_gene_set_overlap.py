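"""Intersect a compound-target list with a disease-gene list.

Builds two small gene lists, normalizes them, and asks whether their
overlap is larger than a random draw from the stated universe would give.
"""

from ibrtox import compare_sets, intersect, normalize_symbols

toxicant_targets = normalize_symbols(
    ["PINK1", "PRKN", "BAX", "BCL2", "CASP3", "NFKB1", "GSK3B", "HDAC1"],
    name="toxicant_targets",
)
disease_genes = normalize_symbols(
    ["pink1", "prkn", "bax", "SNCA", "LRRK2", "PARK7", "CASP3", "TH", "SLC6A3"],
    name="disease_genes",
)

shared = intersect(toxicant_targets, disease_genes)
record = compare_sets(toxicant_targets, disease_genes, n_universe=20000)

print("shared targets:", ", ".join(shared))
print(
    f"overlap {record['both']} of |A|={len(toxicant_targets)}, "
    f"|B|={len(disease_genes)} in a universe of {record['universe']}"
)
print(f"hypergeometric upper-tail p = {record['p_value']:.3g}")
# A tiny p says this many shared genes is far more than chance overlap
# between two random sets of these sizes, the usual justification for
# analysing the intersection further.
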