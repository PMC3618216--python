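# Methods

## Model and procedure

`ppicomplex` treats a PPI network as an undirected simple graph and a
protein complex as a dense sub-graph whose boundary consists of
bottleneck proteins. The detector is a deterministic seed-and-grow
procedure:

1. **Centrality.** Unnormalized shortest-path betweenness for every
   node (Brandes, via networkx): for node v, the sum over unordered
   pairs {s, t} of the fraction of shortest s–t paths through v,
   endpoints excluded. Normalization is irrelevant here because only the
   ranking is consumed; the unnormalized convention keeps the small
   worked examples integer-valued and oracle-checkable.
2. **Bottlenecks.** The top ⌈BC/100 · |V|⌉ nodes by (score descending,
   identifier ascending). The ceiling guarantees a non-empty set for any
   positive BC; BC = 0 is the explicit ablation with no bottlenecks at
   all. Ties at the cut are broken by identifier so runs are
   reproducible.
3. **Close bottlenecks.** C(n) = bottlenecks within distance ≤ 2 of n,
   computed as radius-2 BFS balls from each bottleneck (cheaper than
   from every node when bottlenecks are a few percent). A bottleneck is
   close to itself (distance 0) — required for the seed-singleton
   bookkeeping below.
4. **Growth.** Each node seeds one cluster, seeds processed in
   centrality order. A cluster tracks its shared bottlenecks
   S = ∩ members' close sets (the seed's close set initially) and its
   active frontier (non-bottleneck members; the seed counts as active
   while the cluster is a singleton, even if it is itself a bottleneck —
   otherwise bottleneck seeds could never grow). Per iteration:
   candidates are the frontier's outside neighbours; those keeping
   induced edge density ≥ CC are scored
   density × |S∩C(n)|/|S| × |S∩C(n)|/|C(n)|, and the top
   max(1, ⌈k/100 · eligible⌉) join as one batch, scored against the
   pre-batch cluster (density is not re-checked within a batch). Growth
   stops when no candidate passes the density gate.
5. **Reporting.** Clusters of ≥ `min_size` members are reported and
   their members removed from the seed queue; smaller clusters consume
   only their seed. Removal blocks seeding, not absorption into later
   clusters, so complexes overlap — empirically on the boundary
   bottlenecks. Duplicate member sets are reported once.

Key conventions forced by the worked 11-node example and kept
throughout: the "clustering coefficient" of a cluster is induced-subgraph
edge density 2E/(n(n−1)) (1.0 below two nodes), not average local
clustering — the two-node cluster {D, G} must score 1; and a cluster's
shared-bottleneck set after growth is the intersection over all members,
the reading under which the narrated trace keeps S = {G, C, H} through
{D, E, G}.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `bc_percent` | 1.0 (%) | bottleneck cut; 0 = density-only ablation |
| `cc_threshold` | 0.6 | minimum cluster edge density for growth |
| `k_percent` | 5.0 (%) | eligible candidates admitted per iteration |
| `min_size` | 3 | smallest reportable complex |
| `omega` | 0.2 | affinity threshold for a prediction↔reference match |

The CLI defaults (CC 0.6, BC 1%, k 5) are the regime that performs best
on sparse curated yeast networks; denser, noisier networks (BioGRID-like)
favour a higher CC and more bottlenecks. k up to ~10% mainly trades
speed for granularity and barely moves accuracy.
`tie_admission=True` replaces the top-k% batch with "all candidates tied
at the best score" — the simplification used in the narrated walkthrough;
it exists to make that trace reproducible and is off by default.

## Scoring degenerate cases

With bottlenecks present, a candidate whose close set is empty — or a
cluster whose shared set has emptied — scores 0 (division-by-zero
guard); such candidates can still be admitted when nothing scores
higher, since admission takes max(1, …) of the eligible list. With
`bc_percent = 0` the two ratio terms are dropped entirely and the score
is the density alone; the test suite holds this path equal to an
independently written pure-density grower on random graphs. A `max_iter`
cap (default |V|) bounds growth; membership grows strictly each
iteration, so it normally terminates by candidate exhaustion.

## Synthetic data

`toy_network()` is the fixed 11-node graph used in the worked examples:
a dense core {C, D, E, G, H} whose three hubs C, G, H each also close a
peripheral triangle ({A, B, C}, {H, I, J}, {G, L, M}). It is a
*constructed consistency model* of the published example figure — every
printed fact about that example (G's neighbours D, E, L, M;
close(D) = close(G) = {G, C, H}; density({D, G}) = 1; growth from G
ending at C and H; the four overlapping output complexes) holds on it —
not a claimed reconstruction of the original drawing, whose full
topology is not recoverable.

`planted_network()` emulates what the detector assumes real PPI maps
look like: disjoint dense modules (protein complexes) joined by sparse
connectors, plus uniform false-positive edges. Modules of sizes drawn
from `size_range` get each internal edge with probability
`within_density` (resampled until connected); consecutive modules are
bridged by dedicated connector nodes wired to two members of each side,
with the last module bridging back to the first so the junctions form a
ring; noise edges are then added independently with probability
`noise_p` per remaining pair. Truth complexes are the planted member
sets; connectors belong to none. Defaults — 20 modules of 5–10 nodes,
within-density 0.9, one connector per junction, noise 0.01 — are the
package's standard benchmark conditions; one integer seed fixes
everything and there is no global random state.

The ring rather than an open chain is deliberate: in a chain the
end junctions carry only a sliver of inter-module traffic and their
connectors do not reach the top of the betweenness ranking, whereas on a
ring every junction carries comparable traffic and all connectors rank
in roughly the top sixth of nodes when noise is low. That guarantee is
regime-limited, and the limitation is worth stating: once uniform noise
is dense enough that random shortcuts out-compete the ring for
long-range shortest paths (around noise 0.01 on ~170-node instances),
distal connectors lose their betweenness advantage. Recovery of the
planted modules does not depend on that ranking — the density gate does
most of the work — but claims about *which* nodes are bottlenecks only
transfer to the low-noise regime.

What passing on planted networks does and does not show: the generator
produces clean module structure with Bernoulli noise; real PPI networks
add hub-dominated degree distributions, genuinely overlapping complexes,
and correlated (experiment-specific) false positives, none of which are
modelled. Benchmark results here demonstrate correctness of the search
and scoring machinery, not field performance on a given database export.

## Numerical and design choices

- Everything is deterministic: ties in seeding, bottleneck cuts and
  admission are broken by identifier; two runs on identical input and
  parameters are byte-identical.
- Betweenness is exact, not sampled; the intended scale is
  desk-to-database-export (10³–10⁴ nodes), not whole-interactome meshes.
- Matching is existential on both sides (a complex counts once however
  many partners it has), per the R_hit/C_hit definitions; F1 is defined
  as 0 when recall and precision are both 0.
- `affinity` rejects empty sets rather than defining 0/0.
- Evaluation filters both sides to size ≥ 3 *before* counting, so n_ref
  and n_pred in the report are post-filter counts.
- The acceptance/benchmark problem sizes (11-node fixture; ten ~175-node
  planted instances; random graphs of ≤ 12 nodes for the
  path-enumeration oracle, where explicit enumeration is tractable) were
  chosen as the package's standard verification scale.

## Known limitations

- No merging or post-filtering of highly similar predictions; near-
  duplicate complexes from nearby seeds are reported as-is (only exact
  duplicates collapse).
- Weighted or directed interaction data, PSI-MI XML parsing and
  identifier mapping are out of scope; inputs are bare edge lists.
- Small complexes (size 3–4) sitting entirely inside a dense
  neighbourhood tend to be absorbed into larger predictions — the
  affinity threshold 0.2 tolerates some of this, but the detector has no
  sub-complex resolution step.
- Competitor algorithms (MCODE, MCL, link clustering) are not bundled;
  comparisons require running those tools separately on the same files.
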