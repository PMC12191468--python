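# Methods

## Model

The score is built from a coined discrete-time walk on the 2N-dimensional
space of (coin, node) pairs, coin-major ordering index(c, j) = c·N + j
with the stay sector f = 0 first. Components, in the order they are
applied:

1. **Initial state** ψ(0): all 2N amplitudes equal, normalized to unit
   Euclidean norm (each entry 1/√(2N)). The ranking is provably
   invariant to this global scale — multiplying ψ(0) by c > 0 multiplies
   every score by c² — so the normalization is a convention, not a
   modeling choice; unit norm is used so that the initial state is a
   legitimate quantum state.
2. **Coin** C(j,k) = −A(j,k) + 2/(Pa(j,k)+2), computed for *all* node
   pairs from BFS all-pairs shortest paths. Self-distance Pa(j,j) = 0
   gives the dominant diagonal C(j,j) = 1 (the "stay" amplitude);
   adjacent pairs get −1/3; connected non-adjacent pairs a positive
   value in (0, 1/2] decaying with distance; disconnected pairs take the
   Pa → ∞ limit, exactly 0. The +2 in the denominator keeps the path
   fraction strictly below 1 (the off-diagonal minimum of Pa is 1).
3. **Shift** S = blockdiag(I, Â) with Â the row-normalized adjacency
   (isolated nodes keep a zero row). S is assembled in O(N + M) and is
   *not* unitary: the move sector is an averaging (contracting)
   operator. Probability is therefore not conserved and tests must not
   assert conservation — that property belongs to the genuinely unitary
   ring walk in `oqw_line`, which is kept precisely as the unitary
   reference for the coin/shift machinery.
4. **Evolution** U(t) = [S·blockdiag(C, C)]^t. Since both factors are
   block-diagonal, U(t) = blockdiag(C^t, (ÂC)^t); the implementation
   exploits this and never allocates a 2N×2N matrix in the ranking path.
   Default t = 2: two steps incorporate 2-hop structure, which is the
   scale at which local topological information saturates for tasks like
   link prediction, while longer walks re-introduce the oscillatory
   traceback behavior the self-loop construction is meant to suppress.
5. **Observation** P(j) = (m_jᵀ U(t) ψ(0))², with m_j carrying weight
   |N(k)|/M at every neighbor k of j, duplicated in both coin sectors.
   Vectorized over all nodes this is P = (A · (deg/M ∘ v))² with v the
   evolved per-position sector sum.

Ties in the resulting ranking are broken by ascending node label so that
every run of every command is deterministic.

## Coin-formula variants

The coin definition admits two algebraic readings, and the package ships
both:

- `grover` (default): C = −A + 2/(Pa+2), the reading that mirrors the
  Grover diffusion structure (a constant fraction minus a connectivity
  delta).
- `fraction`: C = (2 − A)/(Pa+2).

On the karate-club benchmark the `grover` form ranks the two faction
leaders first and recovers the canonical top-10 influential set
{1, 2, 3, 4, 8, 9, 14, 32, 33, 34}; the `fraction` form instead demotes
nodes 2, 4 and 8 below peripheral bridges and misses the canonical set.
The `grover` form is therefore the default; `fraction` stays available
behind the `variant` flag for sensitivity analysis.

Two nearby readings were considered and rejected for the default: a
self-loop distance Pa(j,j) = 1 (diagonal 2/3) and an extra application
of U at observation time (U^{t+1}). Neither changes the karate top-6;
both only permute the scores of the four lowest top-10 members, whose
score gaps are 10–20%, and neither is supported by the operator
definitions, so the plain Pa(j,j) = 0, U^t form is kept.

## Complexity

BFS all-pairs shortest paths cost O(N·M) and dominate; the coin is a
dense N×N matrix. This exceeds the O(N⟨k⟩) that would apply if the coin
were restricted to adjacent pairs (where the path term is the constant
−1/3 and carries no information). The full-matrix coin is the
informative object, so it is the default; `max_coin_distance` truncates
the coin at a chosen radius (entries beyond it take the disconnected
limit), restoring near-linear behavior for large graphs at the cost of
discarding long-range path information. Dense linear algebra is used
throughout; a 2000-node, ⟨k⟩ ≈ 8 scale-free graph ranks in a few seconds
on one CPU, and the ranking path never forms a 2N×2N matrix.

## Baselines

- **Degree**: raw |N(j)|.
- **Betweenness**: unnormalized Brandes betweenness via networkx
  (normalization cannot change rank order); validated in the tests
  against brute-force enumeration of all shortest paths on small random
  graphs.
- **PageRank**: own power iteration on the column-stochastic transition
  with uniform teleportation, L1 convergence test (tol 1e-10), damping
  0.85. The damping was validated on the karate club: any value in
  [0.85, 0.99] reproduces the canonical top-10 baseline column
  (34, 1, 33, 3, 2, 32, 4, 24, 9, 14) exactly, while values below 0.85
  replace nodes 9 and 14 with the minor nodes 6 and 7; the standard 0.85
  is pinned. networkx's PageRank is the independent cross-check in the
  tests, not the implementation.

## SIR spreading ground truth

Influence ground truth F(j) is the mean number of ever-infected nodes
at termination of a discrete-time SIR epidemic seeded at j, averaged
over 1000 independent runs per node (the convergence standard in this
benchmarking literature).

- **Dynamics**: synchronous updates; each infected node first attempts
  to infect each susceptible neighbor independently with probability p
  (a susceptible with m infected neighbors is infected with probability
  1 − (1−p)^m, which is distribution-identical to per-contact trials),
  then recovers with probability γ. Infection is resolved before
  recovery within a step, the common discrete-time convention.
- **Recovery**: γ = 1 by default — each node is infectious for exactly
  one step. This is the standard convention in influential-node SIR
  benchmarking, keeps runs short, and is exposed in `SIRConfig` for
  other regimes.
- **Infection probability**: the degree-moment epidemic threshold
  ⟨k⟩/(⟨k²⟩−⟨k⟩) marks the outbreak point; the default p is 1.5× the
  threshold, capped at 1 (karate: threshold 0.148, default p 0.222). A
  fixed multiplier makes cross-network defaults reproducible; any
  explicit p can be passed (`--p 0.3`).
- **RNG**: one master seed; each (seed node, repetition) pair draws from
  its own `SeedSequence(entropy=seed, spawn_key=(node, rep))` substream,
  so per-node results are independent of evaluation order,
  parallelizable, and bit-for-bit reproducible.

## Ranking agreement

Kendall τ is implemented in its τ-a form with strict inequalities: over
all n(n−1)/2 unordered pairs, concordant pairs (both score vectors order
the pair the same strict way) minus discordant pairs, divided by the
total; pairs tied in either vector count in neither. Consequences worth
knowing: τ of a heavily tied vector with itself is below 1 (no
discordances, but tied pairs dilute the numerator), and the result can
differ from `scipy.stats.kendalltau`, which computes the tie-corrected
τ-b. The two agree exactly on tie-free data, which is how scipy serves
as a cross-check in the tests. Averages of τ values are reported to 3
decimals with half-up rounding, matching how such tables are printed.

## Synthetic data and what the tests show

The generators produce Erdős–Rényi G(n, p) and Barabási–Albert graphs
(networkx, seeded). BA graphs reproduce the heavy-tailed degree
distributions of real networks but not their clustering, assortativity
or community structure; ER graphs provide the homogeneous null case.
Passing tests on these graphs and on the embedded karate club therefore
demonstrate correctness of the operators, equivariance under relabeling,
and agreement with closed forms and brute-force oracles — they do not by
themselves establish ranking quality on large real networks, which
requires external datasets (e.g. from network repositories) fed in as
edge lists.

## Numerical choices and degenerate inputs

- Double precision throughout; dense matrices (practical to a few
  thousand nodes).
- Disconnected graphs: cross-component coin entries 0, a warning is
  issued; isolated nodes get a zero shift row, a zero measurement
  vector, score exactly 0, and rank last.
- Empty graphs and empty edge lists are errors; duplicate edges and
  self-loop lines in input files are dropped with a logged warning
  (real edge lists are dirty; the model requires a simple graph).
- Unreachable distances are represented as infinity, never as a large
  finite constant; the coin applies its own limit.
- Diameter is reported over the largest connected component.

## Known limitations

- The full-matrix coin costs O(N·M) time and O(N²) memory; beyond ~10⁴
  nodes use `max_coin_distance` or expect long runtimes.
- Scores are not calibrated across graphs (only within-graph order is
  meaningful).
- The SIR simulator is discrete-time and synchronous; continuous-time
  (Gillespie) dynamics, SI and SIS models are not provided.
- Directed, weighted, temporal and multilayer networks are unsupported.
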