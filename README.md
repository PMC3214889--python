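# ppicluster

Finding candidate assembly factors of a protein complex from physical
protein–protein interaction (PPI) networks.

Very few assembly factors are known for some multi-subunit complexes —
e.g. the mitochondrial respiratory-chain complexes — partly because
classical genetic screens miss factors that are essential for
viability.  `ppicluster` implements a systems-biology alternative:
build an un-weighted PPI network centered on the complex's known
subunits (the *seeds*), partition it into dense sub-graphs, and look at
what is *left over* when the dense sub-complexes are subtracted — the
weakly connected residual proteins that still touch designated *anchor*
subunits are the candidates.

The pipeline stages, each exposed as library functions and as a CLI
subcommand:

1. **Assembly** (`ppicluster.assembly`): merge two interaction-database
   snapshots (simple TSV, BioGRID tab, PSI-MI TAB 2.5 dialects) into a
   seed-centered network — the seeds' level-1.5 neighborhood from one
   source, direct seed interactions from the other, plus the expansion
   joining new proteins into the seeds' environment; genetic
   interactions dropped, identifiers unified, every interaction kept
   once, un-weighted.
2. **Overlapping clustering** (`ppicluster.clusterone`): greedy growth
   from every node under the cohesiveness quality
   `q(C) = m_int/(m_int + m_bnd)` (growth guided by the penalized form
   `m_int/(m_int + m_bnd + 2|C|)`), filtered by size ≥ 3, density
   `m_int/(n(n+1)/2)` ≥ 0.25 and a one-sided Mann–Whitney p-value
   (intra- vs boundary degrees, exact for small clusters) ≤ 0.05;
   clusters with match coefficient `|A∩B|²/(|A||B|)` ≥ 0.8 merged.
3. **Disjoint clustering** (`ppicluster.mcode`): k-core
   vertex-weighting (weight = `k* ×` density of the closed
   neighborhood's highest core) with threshold expansion and haircut —
   used when a branch cannot be split into overlapping sub-graphs.
4. **Candidate discovery** (`ppicluster.discovery`): recursive
   partitioning, subtraction of the disjoint children from their
   parent, and ranking of anchor-connected residual proteins.
5. **Synthetic data** (`ppicluster.synthdata`): planted-module networks
   with anchors, satellite candidates and sparse background, so every
   stage is testable without database downloads.

## Worked example

`examples/04_discover_candidates.py` runs the whole pipeline on the
synthetic discovery scenario (two planted modules of 17 and 8 proteins,
5 satellite candidates wired only to the 2 anchor proteins, 60
background proteins):

```
network: 90 proteins, 243 PPI; 10 seeds

cluster tree (id: size, how the node was split):
  1        n= 34  mcode
  1.1      n= 17  leaf
  1.2      n=  4  leaf
  1.3      n=  4  leaf
  2        n= 15  clusterone
  2.1      n= 12  mcode
  2.1.1    n=  7  leaf
  3        n=  5  leaf
  root     n= 90  clusterone

primary report: parent 1, anchors M1N01, M1N02
protein  edges->anchors  edges->seeds
SAT01                 2             2
SAT02                 2             2
SAT03                 2             2
SAT04                 2             2
SAT05                 2             2

planted satellites: SAT01, SAT02, SAT03, SAT04, SAT05
recovered exactly: True
```

Reading the output: the pipeline found a 34-protein parent cluster
holding both planted modules and the satellites, could not split it
further into overlapping sub-graphs, so split it disjointly into a
17-protein and two 4-protein complexes.  Subtracting those from the
parent leaves a residual whose anchor-connected members — each with 2
edges to the anchor subunits — are exactly the five planted candidates.

The other examples show assembly from heterogeneous snapshot formats
(`01`), the overlapping cluster table with densities, qualities and
p-values (`02`), and the disjoint split of a density-contrast fixture
(`03`).

The same run from a shell:

```sh
ppicluster simulate --seed 1 --out-dir sim/
ppicluster discover --network sim/network.tsv --seeds sim/seeds.tsv --out-dir out/
# candidates: SAT01, SAT02, SAT03, SAT04, SAT05
```

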