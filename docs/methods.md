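# Methods

This note records the model as implemented, the parameter choices and
their rationale, what the synthetic generators do and do not emulate,
and the numerical conventions that affect results.

## Degeneration model

The unit of time is one day (`dt = 1`).  Each day `t`, every HEALTHY
link independently becomes AFFECTED with probability
`p(t) = min(1, p0 + p1·t)`; an affected link is never re-drawn, so the
probability that a given link has ever been affected by day `t` is
`1 − Π_{s≤t}(1 − p(s))`.  Repair is not modelled separately: `p`
represents the net of loss and repair, with loss dominating.

An affected link's strength is recomputed each step from its initial
strength and elapsed time, `ε(t) = ε0·exp(−(t − t_a)/τ)` — never by
repeated multiplication, which would accumulate floating-point drift.
Removal uses `ε ≤ ε0/e` with `exp(−1)` evaluated once, so for integer
τ the link is removed exactly at day `t_a + τ`.  State transitions are
one-way (HEALTHY → AFFECTED → REMOVED).

Parameter defaults (all per day unless noted):

| parameter | default | meaning / origin |
|---|---|---|
| `p0` | 0.01 | initial per-link affection probability (culture scenario) |
| `p1` | 1e-4 | daily increment of the affection probability |
| `τ` | 30 days | decay timescale; 50% spine loss in 3 weeks gives 21/ln 2 ≈ 30.3, hence the range 20–40 |
| `horizon` | 400 days | ample for full breakdown at the defaults |
| `metric_cadence` | 1 | days between expensive metric evaluations (5 is used at N = 10⁴ in scenarios; shortest-path metrics dominate cost) |

The dense-connectome scenario uses `p0 = 0.004`, `p1 = 1e-6` per
*step*; its steps are abstract because no defensible step-to-calendar
mapping exists for the human data, so the package reports step counts
and leaves any calendar conversion to configuration.

## Network generation

**Directed Watts–Strogatz.**  A ring lattice in which node `i` points
to its `k_out` forward neighbours, with each edge's head rewired
independently with probability `q` (self-loops and duplicate edges
rejected and resampled).  Out-degree is exactly `k_out`, so the edge
count is exactly `N·k_out`.  The default `q = 0.1738` was frozen from
the shipped bisection calibration (`calibrate_rewire_prob`) targeting
an average clustering of 0.4 at `N = 10⁴, k_out = 10`; at that point
the directed mean shortest-path length is ≈5.3, consistent with the
small-world regime of cortical networks (clustering ≈0.4, path length
≈5.5).

**Initial weights.**  `identical` sets every ε0 = 1 (the healthy
baseline, so strengths read as fractions of a healthy synapse).
`normal(0.7, 0.2)` rejects-and-resamples outside (0, 1], keeping the
truncated-normal shape exact (mean checked against the closed form).
`lognormal(4, 0.5)` interprets the parameters as the mean/sd of the
underlying normal — the natural reading for a "log-normal with
(μ, σ)" — and rescales into (0, 1) by dividing by the realization's
maximum (times 1 − 1e-9), the simplest map onto the open unit
interval.  A min–max affine rescale is the plausible alternative; it
compresses the distribution's shape and was not chosen.

**Connectome fixture.**  A synthetic stand-in for a mesoscopic
whole-brain parcellation network (360 regions, 43 516 directed
weighted edges): regions on a ring, the `m` ordered pairs with
smallest exponentially-jittered ring distance admitted.  This
reproduces the size, density (~0.34), high clustering (~0.73 ≫
density) and short paths (<2 hops) of such connectomes, plus sparse
long-range shortcuts.  It does **not** reproduce hemispheric
organisation, hub/rich-club structure, or empirical weight
correlations — conclusions about the real human connectome cannot be
drawn from it; it exists so the dense-regime *qualitative* behaviour
(long robust plateau, then rapid collapse; two-slope decline of
normalised global efficiency) is testable without the restricted
source data.

What the small-world generator does not emulate: spatial neuron
morphology, synapse multiplicity, degree heterogeneity beyond the
Poisson-like in-degree of rewiring.  Passing tests therefore validate
the *model dynamics*, not any particular biological network.

## Metrics

All metrics run on the functional subgraph (non-removed links);
affected links participate with their decayed strength, which is what
produces the efficiency decline before any structural break.  A link's
path weight is its resistance 1/ε; pair weights w_ij are single-source
Dijkstra distances (plain BFS when all strengths are exactly 1).

* Global efficiency: mean of 1/w_ij over ordered pairs; unreachable
  pairs count 0, so GE → 0 as the network disintegrates.
* Average path length: mean w_ij over *reachable* pairs only
  (undefined, returned as `None`, when nothing is reachable).  An
  LSCC-restricted variant can be computed by passing the component's
  nodes as `sources`.
* Clustering: average local clustering of the undirected projection,
  by sparse triangle counting; degree-<2 nodes contribute 0.  The
  undirected definition is the one whose ≈0.4 small-world target is
  meaningful.
* Efficiency histograms: right-closed bins (lo, hi], first bin closed,
  default edges 0:0.05:1, so a pair at exactly an edge value counts in
  the bin below (a 4-hop unit path, efficiency 0.25, lies in
  (0.20, 0.25]).
* For `N = 10⁴` all-pairs metrics, a uniform source subsample (800–2000
  sources) gives an unbiased estimate of pair averages and scaled
  counts; the acceptance protocol uses full all-pairs BFS for the
  fresh-network path length and 1000-source samples elsewhere.

## Critical-time estimation

Near breakdown the LSCC fraction is fitted by `f = a·(Tc − T)^β` over
trace points with `0.01 ≤ f ≤ 0.3` and `T < Tc` (the near-transition
window; configurable).  For each grid candidate (Tc from 30 days before
to 10 after the observed breakdown; β ∈ {0.5, 1, 1.5, 2}) the fit is a
least-squares line **through the origin** in the transformed
coordinate — the power law vanishes at Tc, and with a free intercept
every linear trace would fit every Tc perfectly at β = 1, making Tc
unidentifiable.  R² = 1 − SSres/SStot, clamped to [0, 1]; the
(Tc, β) with maximal R² is selected.

Ensembles are fitted per realization and aggregated (modal β, mean
Tc): fitting the ensemble-*mean* trace instead selects β = 1.5–2,
because realizations break down on different days and pointwise
averaging convexifies the tail; the per-realization route recovers the
mean-field β = 1 modally at N ≥ 2000.  Realizations whose collapse
leaves fewer than five points inside the window are skipped (at least
half must fit).  The infinite-size critical time is the intercept of
ordinary least squares of fitted Tc on 1/N.

## Problem sizes used in tests and the acceptance protocol

Finite-size sweep: N ∈ {1000, 2000, 5000, 10000}, out-degree 10,
identical weights, 20 seeded realizations per size; fast-spread
scenario 20 realizations; onset metrics averaged over 5 realizations
with 1000-source path sampling.  These sizes complete in a few minutes
on one CPU while keeping the ensemble dispersion of fitted quantities
around 1–2 days.

## Known limitations

* The collapse completes ~10–15 days later than the 140–160-day
  breakdown window the culture scenario targets: the calibrated
  forward-lattice Watts–Strogatz generator loses its giant SCC at
  functional mean out-degree ≈1.1 (near the random-directed-graph
  threshold of 1), whereas a critical time of ≈150 days would require
  a topology whose giant SCC dissolves at degree ≈1.4 (more
  clustered/reciprocal).  The calibration here pins only the
  clustering coefficient; reciprocity and degree mixing are left free.
* The "onset" marker (first day ensemble-mean f ≤ 0.9, ≈ day 118)
  falls long after the clustering and path-length shifts usually
  associated with disease onset: at that day ~70% of links are already
  removed, clustering is down ~73% and the weighted path length is
  ≈14.  A 25% clustering loss occurs near day 55 and a path length of
  7.35 near days 67–83.  Any onset-dependent quantity is extremely
  sensitive to this (undefined) marker.
* No neuron-level dynamics (firing, plasticity), no explicit repair
  process, no multilayer or time-varying topology.
* Single-run exponent selection is noisy; β should always be read from
  ensembles.
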