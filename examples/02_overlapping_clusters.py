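"""Overlapping clustering of a network with two planted modules.

Generates two dense 10-protein modules sharing 2 proteins, clusters the
network by greedy cohesiveness growth, and prints the cluster table.
Each row gives the cluster size, internal/boundary edge counts, density
(internal edges over n(n+1)/2), quality (internal over all incident
edges) and the one-sided Mann–Whitney p-value comparing members'
intra-cluster and boundary degrees.
"""

from ppicluster import PlantedSpec, cluster_one, planted_network

spec = PlantedSpec(
    module_sizes=(10, 10),
    intra_p=0.9,
    inter_p=0.05,
    overlap_map={(0, 1): 2},  # 2 proteins belong to both modules
    rng_seed=1,
)
network, truth = planted_network(spec)
print(f"network: {network.number_of_nodes()} proteins, "
      f"{network.number_of_edges()} PPI")

result = cluster_one(network)
print(f"{result.n_grown} distinct groups grown, "
      f"{len(result.clusters)} accepted\n")
print("id  n   m_in  m_bnd  density  quality  p-value")
for c in result.clusters:
    s = c.stats
    print(f"{c.cluster_id:2s}  {s.n_nodes:2d}  {s.m_internal:4d}  "
          f"{s.m_boundary:5d}  {s.density:7.3f}  {s.quality:7.3f}  {s.p_value:.2g}")

for i, mod in enumerate(truth.modules, 1):
    best = max(
        result.clusters,
        key=lambda c: len(mod & c.members) / len(mod | c.members),
    )
    j = len(mod & best.members) / len(mod | best.members)
    print(f"planted module {i}: best-match Jaccard {j:.2f}")
# Both planted modules come back as separate overlapping clusters; the
# two shared proteins appear in both.
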