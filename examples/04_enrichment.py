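"""Hypergeometric over-representation analysis of a query gene list.

Builds a small synthetic gene-set collection in which one set is heavily
enriched in the query, then runs the hypergeometric-tail test with
Benjamini-Hochberg correction.  The p-value for a set with K members in a
universe of N, overlapping a query of n genes in k, is P(X >= k) for
X ~ Hypergeometric(N, K, n).
"""

from cernet import ora

universe = {f"g{i:03d}" for i in range(200)}
gene_sets = {
    "mucin_secretion": ("goblet-cell program", {f"g{i:03d}" for i in range(15)}),
    "immune_response": ("broad immune set", {f"g{i:03d}" for i in range(50, 90)}),
    "housekeeping": ("unrelated set", {f"g{i:03d}" for i in range(100, 140)}),
}
query = {f"g{i:03d}" for i in range(10)} | {"g050", "g051"}

table = ora(query, gene_sets, universe, alpha=0.05)
print(table[["set", "k", "K", "n", "N", "p", "q", "significant"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nk/K = overlap/set size; p = hypergeometric tail; "
      "q = Benjamini-Hochberg FDR")
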