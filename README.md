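# netalign

Mix-and-match **global network alignment** for protein–protein interaction
(PPI) networks and other undirected graphs.

Global network alignment (GNA) finds a total injective map
`f : V1 → V2` between the node sets of two networks (`|V1| ≤ |V2|`) that
exposes conserved interaction structure, so that function can be
transferred between species across aligned regions. Most GNA heuristics
factor into two interchangeable parts:

* a **node cost function (NCF)** — pairwise topological similarity between
  nodes of the two networks, and
* an **alignment strategy (AS)** — the search procedure that turns those
  pairwise scores into an alignment.

`netalign` implements two NCFs and two ASs and lets you combine them
freely, so the contribution of each component can be evaluated fairly:

| NCF | AS |
|---|---|
| **Graphlet degree vectors (GDV)** — counts, for each of the 73 automorphism orbits of the 30 connected 2–5-node graphlets, how often a node touches that orbit; nodes are compared by a log-scaled, orbit-dependency-weighted similarity in [0, 1]. | **Linear-assignment seed-and-extend** — seed at the highest-cost pair, then repeatedly solve exact maximum-weight bipartite matchings between the neighborhoods of aligned pairs. |
| **Spectral signatures** — per radius r = 1..k, the binned eigenvalue spectrum of the normalized Laplacian `I − D^(−1/2) A D^(−1/2)` of the node's r-ball; distance is the mean per-level ½·L1 between histograms. | **QAP-aware seed-and-extend** — same skeleton, but candidate weights mix the cross-network cost with a consistency term comparing within-network similarities against already-aligned anchor pairs (`λ·cost + (1−λ)·consistency`). |

Aligner codes follow `NCF-AS`: `M-M` (graphlet NCF + linear AS), `G-M`
(spectral + linear), `G-G` (spectral + QAP-aware), `M-G` (graphlet +
QAP-aware).

On top of that the package provides:

* **sequence/topology blending** `αT + (1−α)S` with α ∈ {0.0, 0.1, …, 1.0},
  where S comes from BLAST-like bit scores normalized by their maximum;
* **neighborhood-size levels** T1–T4 (graphlets on up to 2/3/4/5 nodes;
  1/2/3/4-hop balls);
* **quality measures**: node correctness `NC = |{u : f(u)=h(u)}|/|V1|`,
  edge correctness `EC = |E1∩E2′|/|E1|`, induced conserved structure
  `ICS = |E1∩E2′|/|E2′|`, symmetric substructure score
  `S3 = |E1∩E2′|/(|E1|+|E2′|−|E1∩E2′|)` (all ×100%), the LCCS score
  `√(N·E)` of the largest connected conserved subgraph, and GO / EXP
  correctness of aligned annotated protein pairs;
* a **known-mapping benchmark**: noisy supersets of a base network
  (+x% edges, x = 5..25), evaluation grids over
  (aligner × α × T-level), rank aggregation, and Pearson/Spearman
  correlations between quality measures.

## Worked example

Align a 30-node asymmetric random graph against a 10%-noisy, relabeled
copy of itself using the graphlet NCF and the linear-assignment AS:

```python
import numpy as np
import netalign as na
from netalign.benchmark import make_asymmetric_graph, add_noise, relabel_network

base = make_asymmetric_graph(30, 0.15, rng=np.random.default_rng(7), distinct_gdv=True)
noisy, truth = relabel_network(add_noise(base, 10, rng=np.random.default_rng(8)),
                               rng=np.random.default_rng(9))
T = na.gdv_cost_matrix(base, noisy, "T4")      # 30 x 30 GDV similarities
aln = na.align_seed_extend(base, noisy, T)     # total injective map
report = na.evaluate_alignment(base, noisy, aln, truth=truth)
print(report.to_dict())
```

prints

```
{'NC': 100.0, 'EC': 100.0, 'ICS': 91.4, 'S3': 91.4,
 'LCCS_N': 100.0, 'LCCS_E': 100.0, 'LCCS': 100.0,
 'GO': None, 'EXP': None, 'conserved_edges': 64, 'ics_defined': True}
```

The aligner recovers the hidden node permutation exactly (`NC = 100`):
all 64 base edges are conserved (`EC = 100`), while the 6 noise edges in
the larger network dilute `ICS` and `S3` to 64/70 ≈ 91.4%. `GO`/`EXP` are
`None` because no annotations were supplied — undefined is distinguished
from 0%.

The same pipeline is available from the shell:

```sh
netalign fixtures --kind noisy_series --param n=30 --seed 7 --outdir fx/
netalign align --net1 fx/er30.el --net2 fx/er30_noise10.el \
    --ncf gdv --strategy seedextend --alpha 1.0 --size T4 --out aln.tsv
netalign score --net1 fx/er30.el --net2 fx/er30_noise10.el \
    --alignment aln.tsv --truth fx/er30_truth.tsv --out report.json
netalign bench --config bench.yaml   # full (aligner x alpha x T) grid
```

## File formats

All formats are plain text, documented here by example:

* **edge list** (default): one edge per line, whitespace-separated;
  `#` starts a comment; a lone token declares an isolated node.

  ```
  # my network
  p1 p2
  p2 p3
  lonely_node
  ```
* **LEDA .gw** (undirected, unlabeled-edge subset): header
  `LEDA.GRAPH`, node count, `|{label}|` node lines, edge count,
  `src tgt 0 |{}|` edge lines.
* **pair scores** (e.g. BLAST bit scores): `labelA labelB score` triplets,
  e.g. `YAL001C FBgn0000008 57.4`.
* **annotations**: `protein GOterm [evidence]`, e.g. `p1 GO:0006915 IDA`.
* **alignment**: two columns, smaller-network node then larger-network
  node, e.g. `p1 q7`.

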