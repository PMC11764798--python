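# Methods

## Model and scope

A bit string is an ordered array b = (b₁,…,b_B), bᵢ ∈ {0,1}; the Hamming
distance H(b, b′) counts differing positions.  A similarity network is
built on N *distinct* strings, linking pairs with H ≤ G (1 ≤ G ≤ B).  The
package covers: random distinct string sets (uniform without replacement),
a neutral-evolution generator of such sets, network construction, the
closed-form structural theory (degree law, giant component, clustering,
richness approximation), empirical metrics (components, clustering,
assortativity, geodesic distances) with an Erdős–Rényi comparator, and
realization-averaged experiment drivers.  Out of scope, deliberately:
non-binary alphabets, distance-weighted links, selection pressure, and
dynamical processes running on the networks.

## Parameters

| symbol | meaning | typical values here |
|---|---|---|
| N | nodes / population size | 128–1024 (default sweeps: 1024) |
| B | string length (bits) | 16–100 |
| G | Hamming threshold | 1..B |
| μ = M_G/(2^B−1) | link probability | set by (B, G); discrete in G |
| μ/μ_c, μ_c = 1/(N−2) | distance from percolation threshold | 0–8 in sweeps |
| reps | realizations per grid point | 50 (20–25 for geodesic sweeps) |
| T | elementary evolution steps | quoted in rescaled units T/(N·B) |

μ takes *discrete* values as G varies, and the jumps are large when B is
small (at B=20, N=1024 the ratio μ/μ_c jumps 0.02 → 0.2 → 1.3 → 6.0 for
G=1..4).  Curves against μ/μ_c are therefore reported at the achievable
discrete ratios, never interpolated, and any statement "at ratio ≈ r"
means the nearest achievable ratio.

## Neutral-evolution generator

The population starts as N identical all-zero strings.  One step: pick a
parent uniformly, copy it, flip one uniformly chosen bit, and write the
child over a uniformly chosen victim (the parent itself may die; a flag
redraws the victim if parent and victim coincide — the stationary behavior
is insensitive to this).  Variants: the child may replace its own parent,
or be built by single-point crossover of two distinct uniformly drawn
parents (cut point uniform on the B−1 internal boundaries — the crossover
law is our choice) before the mutation.  Convergence to the random-set
reference f_H = 2^{−B}C(B,H) is tracked by D(T) = Σ_H (f_H(T) − f_H)².

What the generator emulates: mutation–drift balance at constant population
size, i.e. the mechanism by which random string sets arise without
selection.  What it does not emulate: selection, recombination hotspots,
variable population size, back-mutation biases — so agreement of the
network suite on these sets says nothing about networks built on strongly
selected or structured real genotypes.

Two empirical properties of D(T), both computed by the validation suite:
the decay rate in rescaled time T/(N·B) is roughly independent of N and B,
and the late-time plateau is stationary from ≈3 rescaled units on.  The
plateau falls by a factor ≈3.8–3.9 per doubling of N at B=20 — i.e.
D_plateau ∝ N^(−1.9).  This is what the law of large numbers dictates for
a *squared*-difference statistic: each histogram bin fluctuates as ~N^(−1)
(the ~N² pairs are strongly correlated through shared members, leaving ~N
effective samples), so the sum of squares scales as N^(−2).  A sum of
*absolute* differences would scale as N^(−1) instead.

## Exact combinatorics

All binomial-coefficient arithmetic (μ, the clustering triple sum, the
reference histogram) is done in exact integer/rational arithmetic
(`math.comb` + `Fraction`), converted to float only on return: C(100,50)
≈ 10²⁹ overflows any fixed-width integer, and the clustering sum suffers
cancellation in floating point.

Clustering: two neighbors of a node at distances H₁, H₂ have mutual
distance g = H₁+H₂−2h, where h is the overlap of their differing
positions; the number of placements at fixed h is C(H₁,h)·C(B−H₁,H₂−h) of
C(B,H₂) total, and g ≤ G selects h ≥ max(0, ⌊(H₁+H₂−G+1)/2⌋).  The mean
clustering coefficient averages the pair probability over the neighborhood
distance profile with weights C(B,H₁)C(B,H₂), normalized to a probability.
Two conventions are implemented:

- **distinct-pair (default)** — the h = H₁ = H₂ placement, which makes the
  two "neighbors" the *same* string (g = 0), is excluded from numerator
  and normalization (which becomes M_G(M_G−1)).  Network nodes are
  distinct, so this is the quantity the empirical mean clustering
  estimates; it reproduces the exhaustive 2⁷-node full network to 1e−9.
- **as-printed** (`include_identical=True`) — keeps the coincident
  placement with normalization M_G².  The two differ by exactly 1/M_G,
  which matters only at small G (at G=1 the as-printed value is 1/B while
  the true clustering is 0).

Local clustering of degree-<2 nodes is undefined; the default mean
excludes such nodes (an include-as-zero flag reproduces the
`networkx.average_clustering` convention).  Both conventions agree
wherever degrees are healthy; the exclusion convention is the one that
matches the analytic formula in sparse regimes.

## Numerical choices

- **Giant component** — the fixed point u is found by bracketed root
  finding (Brent) on [0, 1−10⁻⁹] with xtol 10⁻¹²; below the critical
  density the solver returns (u, S) = (1, 0) exactly, and a root
  indistinguishable from 1 (asymptotically critical input) is reported as
  u = 1 rather than a spurious tiny S.  The finite-N and large-N forms
  agree in S to <10⁻³ at N = 10⁴.
- **Distances** — all-pairs Hamming distances via the inner-product
  identity with one float32 BLAS call; exact, since all intermediate
  values are small integers (< 2²⁴).  Triangle counts for clustering use
  the same trick (diag(A³)/2).
- **Assortativity** — the symmetric Pearson-over-links form, with the sign
  of the denominator decided in exact integer arithmetic; zero-variance
  (regular) graphs report "undefined" (`None`) rather than 0 or NaN.
- **Geodesics** — unweighted BFS all-pairs via `scipy.sparse.csgraph`;
  the mean runs over unordered same-component pairs only.
- **ER comparator** — G(N, M) with exactly M = round(μN(N−1)/2) uniformly
  placed links, so comparator and similarity network share their degree
  law exactly.
- **Sampling distinct strings** — rejection sampling of uniform random
  strings with a seen-set (uniformity is unaffected by discarding
  duplicates); when the request exceeds half of a small space (B ≤ 24) the
  full enumeration is sampled without replacement instead.
- **Seeds** — every realization's generator derives from
  `SeedSequence((master_seed, experiment_tag, grid_key, replicate))`, so
  whole sweeps and single grid points replay bit-identically.
- **Plateau estimator** — mean of the recorded D over the final 20% of
  record points (recording default: every N·B/100 steps; the O(N²)
  histogram is recomputed only at record points).

## Study conditions and problem sizes

Default experiment conditions are N = 1024 networks averaged over 50
realizations (B = 20, 30, 50 for the threshold sweeps; B = 100 with 20–25
realizations for the geodesic sweep, whose per-point cost is dominated by
all-pairs BFS); the evolution runs use N ∈ {256, 512, 1024}, B = 20, 50
seeds, 6 rescaled time units.  The geodesic threshold grid covers every G
with μ/μ_c ∈ [0.005, 8] plus G = B/2, 3B/4, B, so both flat ends
(L ≈ 1) and the transition window are probed.

## Findings the validation suite quantifies

- Degree law, clustering, richness (below the transition) and the
  supercritical giant component match theory at their stated tolerances.
- **Near the percolation transition the giant component of similarity
  networks is genuinely smaller than the random-graph prediction** at
  these N: at B=20, μ/μ_c ≈ 1.32 the 50-realization mean largest-component
  fraction is ≈0.23 against S ≈ 0.44, while a matched ER ensemble
  reproduces S within one standard error.  The metric-induced clustering
  (C ≈ 0.11 there) spends edges on triangles that do not extend the
  component.  The effect fades away from the transition (at μ/μ_c ≈ 6 the
  agreement is at the 10⁻³ level, and at B=100, μ/μ_c ≈ 1.8 the gap is
  within three standard errors).
- **Degree assortativity** peaks below G/B = 0.5 and decreases with B; the
  peak 50-realization mean is ≈0.17 at B=20 (a 200-realization estimate
  puts it at 0.171 ± 0.002), ≈0.12 at B=30, ≈0.11 at B=50.  The matched
  ER comparator is null (|mean A| < 0.02 wherever z ≥ 1).
- **Mean geodesic distance** peaks at μ/μ_c ≈ 1.8 (the achievable ratio in
  [1, 2] at B=100, N=1024), is ≈1 at both ends of the sweep, and overlaps
  the ER comparator within ±1 SD bands throughout the transition window
  μ/μ_c ∈ [0.3, 4]; beyond it (μ/μ_c ≈ 6) the bands shrink to ~0.04 and a
  small clustering-induced excess (~+0.07) becomes resolvable.
- **Divergence plateau scaling** is ∝ N^(−1.9), as expected for a
  squared-difference statistic (see above), not ∝ N^(−1).

## Known limitations

- Dense-matrix graph representation: memory is O(N²); fine to N ~ several
  thousand, not for very large networks.
- The evolution loop is event-by-event (Python-level); ~10⁷ steps/minute.
  Rescaled-time windows beyond ~20 units at N ~ 10³ get slow.
- No analytic assortativity or geodesic distance — both are simulation
  quantities here.
- Exhaustive oracles (`all_strings`, `enumerate_within`) are exponential
  in B and intended for B ≲ 16.
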