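# Methods

## The model

A population of N swarmer cells is a fixed vertex set; a side-by-side raft
contact between two cells is an undirected, unweighted edge. Three
constraints define the state space:

- no self-contacts (no loops);
- at most one contact per pair (simple graph);
- at most two contacts per cell (degree cap 2), reflecting that rafting
  cells align side by side in chains.

The degree cap forces every connected component to be a simple path or a
simple cycle. The cap is held as a named constant, but only the value 2 is
supported or tested; cycles are permitted (the edge rules allow closing
them) and are reported with their component kind so their contribution to
raft counts can be audited separately.

The population evolves in discrete timesteps under one of three update
rules (Models 1–3, see the README). Models 1 and 2 are monotone graph
processes — the edge set only ever grows — so "some component has ≥ m
cells" is a monotone property and its hitting time

    τ(m) = min{ t ≥ 0 : the largest component has ≥ m cells }

is a well-defined stopping time. Model 3 removes edges (cell death) and is
treated purely as a stochastic simulation: none of the monotone-property
theory is applied to it.

### Assumptions worth stating

- Cells have no spatial positions; "any pair may interact" is the dense
  consolidation-layer limit.
- The population size N is constant. Death (Model 3) empties a cell's
  contacts but keeps its vertex slot, so the dead cell is indistinguishable
  from a newborn isolated cell; an explicit birth process would duplicate
  the existing edge-addition step.
- Time is measured in sweeps and is not comparable across models: a
  Model 1 step proposes one pair, a Model 2/3 step sweeps all ~N²/2 pairs.

## Simulation semantics and numerics

**Model 2/3 sweep.** The definition visits every unordered pair once per
timestep with the degree state updated immediately, so an edge added early
in a sweep can block a later candidate. The order of visits is uniformly
random each sweep (a fixed lexicographic order would systematically favour
low-index cells whenever degree-cap collisions occur; cells are
exchangeable). The implementation does not iterate over all pairs: it draws
the Binomial number K of Bernoulli(P) successes among the pairs eligible at
sweep start, selects those K pairs uniformly without replacement, and
resolves them in random order with the full rule checks. Because failed
trials and pairs ineligible at their visit change nothing, the resulting
graph law is identical to the pair-by-pair sweep, at O(K) instead of O(N²)
per step. No Bernoulli draw is consumed for pairs rejected by the
self/exists/degree rules, keeping the random stream independent of graph
state for rejected pairs.

**Eligible-pair counting.** With u vertices of degree < 2 and s isolated
two-cell components, the eligible pair count is C(u,2) − s, since an
existing edge has both endpoints below the cap only if it is an isolated
edge. This makes saturation (no eligible pair) cheap to detect; Model 1
runs check it every 512 steps when early stopping is requested, and a
saturated trajectory is padded with its frozen terminal values (the state
provably cannot change again).

**Giant-component tracking.** Monotone models use an incremental
union–find; Model 3 recomputes components by traversal each step since
edges disappear.

**Randomness.** All runs use numpy's PCG64 generator. Replicate r of a run
with master seed s uses `SeedSequence(s, spawn_key=(r,))`, so runs are
bit-reproducible per platform and replicates are independent streams.

## Observables

Per timestep: edge count, average degree 2E/N (each undirected edge counted
once, i.e. half the symmetric adjacency matrix), and giant-component size.
Component-size multisets are recorded at user-chosen snapshot times
(default 500, the standard comparison point for the P sweep). Hitting times
are right-censored at the horizon and reported as censored — never imputed;
the gamma fit drops censored samples and logs the censoring fraction.

## Closed-form layer

For a dense clump of n cells with per-pair probability c/n and threshold m
(1 ≤ m < n):

- realizability: c ≥ c_min = |ln(1 − m/n)|. The relation m ≥ (1 − e^(−c))·n
  is checked with an explicit absolute tolerance (default 0: strict),
  because boundary intensities quoted at limited precision overshoot the
  inequality by ~n × rounding error.
- hitting curve: P(t) ∝ t·q·(1 − q)^(t−1) with q = c/n (c minimal by
  default). This is proportional to a lower bound, not a normalized
  density; its total mass over t = 1, 2, … is 1/q.
- cumulative form: the partial sum has the closed form
  (1 − (1−q)^T (1 + qT))/q; normalized by 1/q it is a proper cdf (the
  unnormalized plateau is available behind a flag for figure reproduction).
- mode: treating t as continuous (as the derivative does), the maximum sits
  at t_mode = −1/ln(1 − q); it diverges as n → ∞ at fixed m/n, matching the
  intuition that very large clumps take arbitrarily long to raft. The cdf
  uses integer steps; the derivative and mode use continuous t.
- exact sampling: the normalized law t·q²·(1−q)^(t−1) is the law of
  G₁ + G₂ − 1 for independent Geometric(q) variables, which is how
  `sample_hitting_times` draws without truncation.

## Gamma matching

(k−1)! is implemented as Γ(k) so non-integer shapes are admitted. The
first-order matching and its inverse,

    C ≈ t^k / (2·A·Γ(k)·θ^(k+2) + t^k),
    A = (1/C − 1) / (2·Γ(k)·θ^(k+2)),

form an exact inverse pair (with the small-k simplification t^k ≈ 1), so
threshold ↔ gamma-parameter round trips are identities to machine
precision. The t-dependent threshold curve m(t) = n·(1 − e^(−n·C(t)))
follows from inverting C = |ln(1−m/n)|/n; its relative variation over
t ∈ [1, 10] vanishes as k → 0, which is what licenses reading a single
threshold off a gamma fit.

Two caveats are deliberate design choices. First, the printed grouping of
the matching constant is ambiguous in its source; we canonicalize the chain
so that the pair above is self-consistent, and audit the Γ(k), θ^(k+2) and
factor-2 pieces with a numeric series fit at A = 1 (where every reading
coincides) rather than trusting typography. Second, a negative fitted A is
permitted with a warning — A is a pure proportionality constant — but no
negative A can map to a threshold fraction in (0, 1), and the historical
worked value of A ≈ −3.06 × 10⁻⁶ for *P. mirabilis* strain PM23 is
documented as non-reproducible (its underlying k, θ were never published).

The gamma MLE itself is scipy's, with location pinned at 0; A is a
least-squares scale between the empirical density histogram and the unit
gamma density; goodness of fit is a Kolmogorov–Smirnov statistic. At least
20 positive, non-constant samples are required.

## Exact oracle

For N ≤ 5 cells all labelled degree-capped graphs are enumerated by brute
force over edge subsets (41 states at N = 4), and the Model 1 kernel is
assembled in exact rational arithmetic from the N² equiprobable ordered
draws. Expected hitting times come from the absorbing-chain linear system
(I − Q)x = 1 (solved in floating point with the residual checked); the
hitting distribution comes from forward iteration. Labelled states are the
correct reference because the simulator acts on labelled vertices.
Enumeration for Models 2/3 is out of scope (the per-sweep branching factor
is astronomically larger); Model 2 correctness rests on the Binomial-mean
law of the first sweep, the invariant suite, and stochastic dominance in P.

## Synthetic data and what a green test establishes

There is no external data: every input is generated by the package itself.
The default configurations are the documented ones — N = 1000 with 10
replicates at full scale (N = 200, 3 replicates reduced), P = 10⁻⁴ where a
figure does not state one, snapshots at t = 500, the P grid
{10⁻⁶ … 10⁻²}, and a death-rate grid {0.001, 0.01, 0.1} chosen to span weak
to strong suppression (the source values are unpublished; only the
qualitative claim — no convergence by t = 10,000 — is checked). Green tests
therefore establish internal consistency of the stochastic models with
their exact small-system law and the closed-form layer; they do not
calibrate any parameter against real swarm-front measurements, and the
graph abstraction itself (no space, no motility, no cell elongation
dynamics) is untested against imagery.

## Known limitations

- Model 1 can strand a lone open vertex or an isolated edge, leaving the
  terminal average degree marginally below 2 (2 − O(1/N)); limits are
  therefore tested with tolerance 0.05.
- Hitting times are resolved on the recorded per-step grid; sub-step
  resolution is meaningless in a discrete-time model but the cdf/mode
  continuum treatment means theory and simulation "times" should only be
  compared qualitatively.
- The theoretical q = c_min/n and the simulation parameter P of Model 2 are
  related but not equated anywhere; both are exposed and may be compared
  empirically, with no equivalence claim.
- Degree caps other than 2 are not supported.
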