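"""Test whether CIS genes cluster inside a co-expression network.

Builds a synthetic expression study whose network chains the 7 CIS genes
together, then asks how unusual their mean nearest-member path distance is
against random gene sets of the same size.
"""

from cisnet.network import cis_neighbourhood, permutation_cluster_test
from cisnet.simulate import simulate_expression

study, network, truth = simulate_expression(n_genes=300, n_samples=120, seed=5)
cis_genes = list(truth.planted_signs)

result = permutation_cluster_test(network, cis_genes, n_perm=10_000, seed=9)
print(f"CIS genes: {', '.join(result.genes_used)}")
print(f"observed mean distance to nearest CIS gene: {result.observed:.3f}")
print(f"null mean over {result.n_perm} random sets:  {result.null.mean():.3f}")
print(f"empirical p = {result.p_value:.4g}")
# A small p says the CIS genes sit closer together in the network than
# random gene sets do - the signature of a co-regulated module.

neighbourhood = cis_neighbourhood(network, cis_genes)
print(f"CIS neighbourhood subgraph: {neighbourhood.number_of_nodes()} genes, "
      f"{neighbourhood.number_of_edges()} edges")
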