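# ioqw — quantum-walk-inspired influential-node identification

`ioqw` identifies influential nodes (super-spreaders, critical proteins,
key infrastructure) in undirected, unweighted networks with a
discrete-time coined-quantum-walk construction, and ships the standard
evaluation stack used in this literature: classical centrality baselines
(degree, betweenness, PageRank), a discrete-time SIR spreading simulator
for dynamical ground truth, and ranking-agreement statistics
(Kendall τ-a, top-k overlap).

It is aimed at network scientists who want a reproducible implementation
of the walk-based score together with everything needed to benchmark it
against classical centralities on their own edge lists.

## The method

A walker on a one-dimensional lattice has exactly two directions. The
method transfers this to an arbitrary graph *G* with *N* nodes and *M*
edges by treating each node's neighborhood as a single compressed
direction and adding a conceptual self-loop, so every node offers the
walker two moves: *stay* (coin state |f⟩) and *move into the
neighborhood* (coin state |b⟩). The state space is 2*N*-dimensional
instead of the 2*M* or *N*² of earlier walk-based centralities.

With A the adjacency matrix, Pa(j,k) the shortest-path length, |N(j)|
the degree of j, the operators are

- **coin** C(j,k) = −A(j,k) + 2/(Pa(j,k)+2) — a Grover-diffusion-style
  blend of connectivity and path information (adjacent pairs −1/3,
  diagonal 1, distant pairs decaying toward 0, disconnected pairs 0);
- **shift** S = blockdiag(I, Â), Â(j,k) = A(j,k)/|N(j)| — identity on
  the stay sector, the random-walk transition matrix on the move sector;
- **evolution** U(t) = [S·blockdiag(C, C)]^t with t = 2 by default,
  which reduces to blockdiag(C², (ÂC)²);
- **observation** P(j) = (⟨ĵ| U(t) |ψ(0)⟩)², where |ψ(0)⟩ is the uniform
  unit vector and ⟨ĵ| weights each neighbor k of j by |N(k)|/M in both
  coin sectors.

P(j) ≥ 0 is node j's influence score; ranking is by descending score.
The walk is deliberately non-unitary (S contracts the move sector), so
scores are not a probability distribution — only their order matters.
Two steps are enough to mix 2-hop structure while suppressing the
traceback oscillations that destabilize longer quantum walks.

## Worked example

The package embeds Zachary's karate club (34 nodes, 78 edges, two
factions led by nodes 1 and 34):

```python
import ioqw

g = ioqw.load_fixture("karate")
scores = ioqw.rank_nodes(g, t=2)
for rank, node in enumerate(scores.ranking[:10], 1):
    print(f"{rank:2d}  {node:>2}  {scores.scores[node]:.4f}")
```

prints

```
 1   1  585.2902
 2  34  518.2317
 3   3  388.0315
 4  33  337.8500
 5   2  247.9251
 6  14  192.4117
 7   9  186.3301
 8   4  169.7292
 9  32  154.4379
10   8  122.4682
```

The two faction leaders (1, 34) come first, followed by their
lieutenants (3, 33, 2) and the community-bridging nodes 14, 9 and 32.
Comparing with the PageRank baseline:

```python
pr = ioqw.pagerank(g)                      # damping 0.85
pr.top(2)                                  # ('34', '1')
ioqw.top_k_overlap(scores.ranking, pr.ranking, 10)   # 9
```

nine of the walk's top-10 nodes are shared with PageRank's top-10.

The same pipeline is available from the shell:

```bash
ioqw rank --fixture karate --steps 2 --out walk.csv
ioqw baseline --fixture karate --method pagerank --out pr.csv
ioqw eval walk.csv pr.csv --metric topk --k 10     # -> overlap,k = 9,10
ioqw sir --fixture karate --p auto --runs 1000 --seed 1 --out sir.csv
ioqw eval walk.csv sir.csv --metric tau
```

`ioqw rank` accepts any whitespace- or comma-delimited edge list via
`--edge-list`; `--fixture` provides karate, triangle, path3, star(n) and
cycle(n). `ioqw sir` estimates each node's spreading power F (mean
final epidemic size over repeated SIR runs seeded at that node), the
dynamical ground truth that structural rankings are judged against.

## Scope

Undirected, unweighted, simple graphs only. Directed, weighted,
temporal and multilayer networks, as well as the internals of other
quantum centralities (quantum PageRank, Grover walks, continuous-time
quantum centralities) and of the CDP/DLC/ISBC classical indices, are out
of scope; published complexity figures for those methods are: degree
O(M), betweenness O(N³), CDP O(M + N⟨k⟩), DLC O(N³), ISBC O(N² + N⟨k⟩),
against O(N⟨k⟩) per stage claimed for the walk score (the full-matrix
coin used here actually costs O(N·M); see `docs/methods.md`).
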