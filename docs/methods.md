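# Methods

## Targeted attack

An attack removes edges one at a time in rank order of a per-edge property
(tract length or tract density, increasing or decreasing) and records the
giant-cluster fraction P against the mean degree ⟨k⟩ = 2E/N after every
removal. Two conventions matter and are fixed here:

* **N is frozen.** P is always normalized by the post-pruning node count, so
  ⟨k⟩ decreases by exactly 2/N per step and curves from different subjects
  are comparable. Regions with no tracts are pruned first; if the pruned
  network is still disconnected the attack proceeds with a warning (the
  P = 1 starting premise is checked, not enforced).
* **Ranks are frozen.** The attacked property does not change during
  removal, so ranking once before the attack is identical to re-ranking the
  "currently smallest" edge at every step.

Ties — ubiquitous for streamline count 1 in real data — are broken by a
seeded uniform shuffle of each tie group. This makes tie ambiguity visible
as seed-to-seed curve spread instead of hiding it behind an arbitrary stable
sort; for tie-free weights the curve is seed-independent (tested).

The curve is computed by adding edges in reverse removal order under a
size-tracking union-find (path halving + union by size), O(E α(N)) overall.
The forward definition — recompute connected components after every removal
— is normative; the test suite checks the two agree edge-for-edge on random
graphs, using networkx's component search as the independent oracle. The
union-find also maintains the component-size multiset incrementally, giving
a per-step census of secondary clusters (non-giant components of size > 1);
the census snapshot can be disabled for large curves.

## GCSP theory

The growth rule has one parameter, α > 0: a new edge is α times more likely
to occupy an available in-cluster spot than an available branch to an
unplaced node, all spots counted individually. Its three faces are
implemented and cross-checked against each other:

1. the branching probability (exact combinatorial form, finite N);
2. the discrete master equation evolved exactly from p(n|0) = δ_{n,1},
   with probability-mass conservation asserted to 1e−12 at every step
   (infeasible states n(n−1)/2 < E carry exactly zero mass by construction);
3. the large-N closed form via the principal Lambert-W branch.

The printed rendering of the closed form is typographically ambiguous in the
prefactor and exponent grouping; the implementation fixes the grouping as
P = 1 + (1−2/α)⁻¹ W₀((2/α−1) e^{2/α−1} e^{−⟨k⟩/α}), the unique reading that
satisfies P(0) = 0 and solves the characteristic ODE
f′ = (1−f)/(2−(2−α)f). This is enforced by a property test comparing the
closed form against high-accuracy `solve_ivp` integration (≤ 1e−6 over
κ ∈ [0, 100] for α ∈ {3, 5, 11, 15, 30}) rather than assumed. For α > 2 the
W argument lies in (−1/e, 0] (asserted at runtime); for α < 2 it is
positive, so the same branch applies; α = 2 is the removable singularity
P = 1 − e^{−κ/2}, taken as a limit branch within |α−2| < 1e−8. α ≤ 2 is
mathematically valid but outside the regime of all brain fits (α ≫ 2).

Initial slope is dP/dκ = 1/2 for every α, and the curve has no critical
point: P > 0 for every κ > 0, in contrast to the random-graph form, which is
0 up to ⟨k⟩ = 1 and equals the nonzero fixed point of P = 1 − e^{−⟨k⟩P}
above it.

Finite-size behaviour: at N = 727, α = 11 the master-equation mean E[n]/N
stays within 0.005 of the closed form for κ ∈ [1, 50] (tested at the 1%
level); the gap shrinks with N.

## Fitting α

The attack curve is resampled onto n_points equidistant ⟨k⟩ values on
[0, k_max], k_max being the intact network's mean degree, with a
step-function convention: each grid point takes the P of the recorded step
whose ⟨k⟩ is the smallest value at or above it (attack curves are genuine
step functions; no interpolation). α then minimizes the sum of squared P
residuals against the closed form. Defaults: n_points = 20 and search bounds
(2.05, 60); both are exposed, since the sampling density used for the
original fits is not pinned down anywhere. The optimizer is a coarse grid
scan (step 0.05) followed by bounded golden-section refinement — the
objective costs microseconds, and the scan avoids assuming unimodality.
Refitting an exactly generated curve returns the generating α to < 0.01 with
sse < 1e−10; a curve with constant P raises a fit error. Each attack
property is fitted separately (length and density fits are reported per
subject; no joint fit). Spearman rank correlation (scipy, tie-corrected,
t-approximation p-value) is provided for cohort-level covariate analysis.

## The EPD generator (synthetic data)

The generator's defaults are the published simulation conditions: N = 727
nodes (Talairach parcellation size), α = 11, growth to final mean degree
100, coordinate inflation 1.0001 per edge addition, density growth 1.001 per
edge addition. These defaults are what the acceptance study runs; they are
not tuned.

Decisions the growth rules leave open, fixed here as package defaults:

* **In-cluster spot choice**: uniform over absent in-cluster pairs, drawn by
  rejection sampling — this matches the spot counting in the branching
  probability exactly. (Acceptance ratio never falls below ~0.85 at the
  default edge density.)
* **Branch target**: the recruited node is drawn uniformly from the
  unplaced labels, and attaches to a uniformly random cluster node.
* **Newborn coordinates**: drawn uniformly in the *uninflated* unit ball at
  the recruiting step; the inflation following that same step already
  applies to the newborn. Inflation is accumulated lazily as one scale
  factor per birth epoch (coords · s^{T−t+1}); this equals naive per-step
  multiplication to well below 1e−9 relative.
* **Edge lengths** are Euclidean distances between *final* coordinates —
  inflation lengthens existing edges, so length tracks current geometry.
* If growth ends before every node is recruited (possible below the default
  final ⟨k⟩), the leftover regions are edgeless isolates with uninflated
  positions; the default parameters recruit all 727 nodes in almost every
  run. Completion is almost-sure, not certain: the exact master equation
  puts the expected number of unrecruited nodes at ~0.017 per run at the
  default endpoint, i.e. roughly one run in sixty ends at P = 726/727.

Because each edge's density is multiplied by a fixed factor at every later
addition, final densities are strictly ordered by age, and the
increasing-density attack is *exactly* the time-reversed growth trajectory
(tested point-for-point). The increasing-length attack only approximately
reverses growth (mean |ΔP| < 0.05 at default scale) — coordinate randomness
scrambles the length order relative to the creation order — which is why the
fitted α from distance attack runs higher than from density attack. In the
50-run study the package reports mean fitted α ≈ 10.6–10.9 (density) and
≈ 11.8–11.9 (length).

What the generator emulates: single-cluster growth, the length/density age
gradients, and attack-curve phenomenology with α in the empirical 10–16
range. What it does not emulate: anatomical geometry (hemispheres, bundle
topology), the empirical anticorrelation structure between length and
density beyond what aging induces, measurement noise in tractography, or
developmental growth-rate schedules (α is constant). Passing tests therefore
validate the mechanism and the machinery, not any claim about real
connectome data, which require restricted-access cohorts.

## Comparison generators

Erdős–Rényi G(N, M) (networkx), nonlinear preferential attachment
(hand-written; arriving nodes attach m edges ∝ degree^exponent, uniform
fallback when all weights vanish), Watts–Strogatz rings with chord-distance
edge lengths, and spatially embedded uniform random graphs in the unit ball.
Known closed forms serve as oracles in tests: ring-lattice clustering
3(k−2)/(4(k−1)), the ER clustering expectation ⟨k⟩/(N−1) ≈ 0.0412 at
N = 727, ⟨k⟩ = 29.9 (≈ 0.04, far below the ~0.60 reported for brain
networks), the PA trajectory slope 1/(2m), and the abrupt percolation drop
of the p = 0 lattice at ⟨k⟩ = 2 that the GCSP curve lacks.

## Problem sizes and numerics

The simulation study uses 50 independent EPD runs (the original figure used
1,000; the 50-run mean of fitted α has a standard error below 0.1, ample for
the ±1.5 bands, and the run count is a flag). Unit tests use reduced scales
(N = 100–500) chosen so each property is still sharply resolved. All
generators take explicit integer seeds and are bit-reproducible; pipeline
reports embed config, seed and package version. Dense master-equation
vectors are used without truncation (N up to a few thousand is fine).
Degenerate inputs: empty edge sets yield single-point curves; constant-P
curves raise fit errors; duplicate edge-list rows are an error, not a merge;
matrix dialects require symmetry to 1e−9 and matching edge sets between the
length and density matrices.
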