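# ppicomplex

Overlapping protein-complex detection in protein–protein interaction
(PPI) networks, guided by bottleneck proteins.

## The problem

Protein complexes appear in a PPI network as dense sub-graphs: their
members interact with each other far more than with the rest of the
network. Plain density-based search, however, does not know where one
complex ends and the next begins. *Bottleneck* proteins — the nodes with
the highest betweenness centrality, through which many shortest paths
run — tend to be the connectors between functional modules, so a
sub-graph whose boundary is made of bottlenecks is a far better complex
candidate than an arbitrary dense blob. `ppicomplex` turns that
observation into a seed-and-grow clustering algorithm for anyone who
wants to predict complexes from an interaction map (yeast, human, or any
organism with an edge list) and validate them against a reference
catalogue such as MIPS, CYC2008 or CORUM.

## The algorithm

Let *BC* (percent) define the bottleneck set: the top *BC*% of nodes by
unnormalized betweenness centrality. Every node *n* keeps its **close
bottlenecks** *C(n)* — bottlenecks within shortest-path distance 2 (a
bottleneck is close to itself). A cluster keeps its **shared
bottlenecks** *S*, the intersection of its members' close sets,
initialized to the seed's close set.

Seeds are taken in order of decreasing betweenness. From the current
cluster, every neighbour *n* of an *active* (non-bottleneck) member that
keeps the cluster's edge density

  CC = 2·E / (m·(m−1))   (m members, E induced edges)

at or above the *CC* threshold is scored

  score(n) = CC(members ∪ {n}) · |S ∩ C(n)| / |S| · |S ∩ C(n)| / |C(n)|

and the top *k*% of eligible candidates join per iteration (default
*k* = 5; at least one joins whenever any is eligible). Bottleneck
members never generate new candidates — **the search ends at
bottlenecks**, which therefore become the boundaries of complexes.
Clusters with at least 3 members are reported and their members leave
the seed queue; because removal only blocks seeding, not later
absorption, neighbouring complexes naturally overlap on their shared
boundary bottlenecks. With *BC* = 0 there are no bottlenecks and the
score degenerates to the density term alone (the CC-only ablation).

Predictions are matched to a reference by the affinity score
aff(A, B) = |A ∩ B|² / (|A|·|B|); a complex counts as matched when some
partner reaches aff ≥ 0.2, giving Recall = R_hit/|R|,
Precision = C_hit/|C| and F1 their harmonic mean, with both sides
filtered to complexes of size ≥ 3.

## Worked example

Generate a planted benchmark (20 dense modules of 5–10 proteins on a
ring of connector nodes, 1% noise edges), detect complexes, and score
them against the planted truth:

```sh
ppicomplex simulate --n-complexes 20 --seed 42 --out-prefix demo
ppicomplex detect --ppi demo.edges.tsv --bc 5 --cc 0.6 --out demo.pred.tsv
ppicomplex evaluate --pred demo.pred.tsv --ref demo.truth.tsv
```

prints (data to stdout, logs to stderr):

```
INFO wrote 175 nodes / 733 edges, 20 truth complexes
INFO demo.edges.tsv: 175 nodes, 733 edges
INFO detected 35 complexes (>= 3 members) from 175 nodes / 733 edges
n_pred	n_ref	r_hit	c_hit	recall	precision	f1	omega
35	20	20	29	1.0000	0.8286	0.9062	0.2000
```

All 20 planted modules are recovered (recall 1.0); 29 of the 35
predictions match a planted module at affinity ≥ 0.2 (precision 0.83) —
the unmatched ones are mostly fragments straddling ring junctions. Every
`detect`/`simulate` run also writes a JSON manifest (parameters, input
checksums, counts) that reproduces the run byte-for-byte.

The same from Python:

```python
import ppicomplex as ppc

net, bottlenecks, expected = ppc.toy_network()   # 11-node worked example
found = ppc.detect_complexes(net, ppc.DetectParams(cc_threshold=0.6),
                             bottlenecks=bottlenecks)
sorted("".join(sorted(c)) for c in found)
# ['ABC', 'CDEGH', 'GLM', 'HIJ']  — overlapping at bottlenecks C, G, H
```

Real PPI data enters as a two-column TSV edge list (or SIF) — the form
DIP/BioGRID/I2D exports reduce to once you extract the two identifier
columns — via `ppicomplex detect --ppi interactions.tsv ...`, and
references as flat one-complex-per-line files.

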