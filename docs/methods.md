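# Methods

This note documents the models, conventions and numerical choices behind
`careflow`, and what the synthetic validation does and does not show
about real hospital data.

## The transfer-network model

An inpatient episode ("admission") is a time-ordered sequence of
locations — emergency department, wards, theatres, investigation suites
— reconstructed from timestamped location records. Each consecutive
change of location within one admission is a **transfer**. Locations are
nodes; the directed edge (u, v) carries an integer weight w(u, v)
counting how often the transfer u→v occurred across all admissions.

Conventions, fixed once:

* **No self-edges.** Consecutive records of the same location are a
  continued stay, not a transfer; journeys are compacted before network
  construction, and the same compaction is re-applied after mapping
  locations to care categories (a move between two wards of one category
  is not a category-level transfer).
* **No per-admission de-duplication.** A patient shuttling
  ward ↔ CT three times contributes six transfers: each transfer is a
  distinct use of resources (porters, staff, handovers).
* **Virtual endpoints.** With endpoints enabled, every journey is
  wrapped as ADMISSION → … → DISCHARGE. This makes weighted in-flow
  equal out-flow at every real node exactly — every patient who enters a
  ward later leaves it — a conservation law the tests assert on
  simulator output. The ward-level network defaults to endpoints off,
  the categorised network to endpoints on (the category-level
  convention shows admission and discharge as explicit nodes).
* **Ordering ties.** Two records of one admission with identical entry
  times cannot encode a true order. They are ordered deterministically
  (exit time, then lexicographic location) and the admission is flagged
  in the rejects report. Rows with inverted intervals, unparseable or
  offset-bearing timestamps are rejected row-by-row with reasons, never
  silently dropped. Events without an exit time are kept: ordering uses
  entry times only.

## Node and global measures

* Degree k counts **distinct neighbours** in the undirected view;
  k_in/k_out count distinct senders/receivers. Strength s is the sum of
  incident edge weights (s_in + s_out). The term "strength" is
  occasionally used in the applied literature for other weight-degree
  combinations; this package uses the standard weighted-degree
  definition throughout, which is the one the strength–degree scaling
  analysis requires.
* Net connectivity Δ = k_in − k_out. Positive Δ marks "receiver" wards
  (fed from many places, discharging to few), negative marks
  "distributors". The sign convention is chosen so receivers are
  positive.
* Clustering (local and global transitivity) and the weighted
  nearest-neighbour degree knn_w(i) = (1/s_i) Σ_j w_ij k_j are computed
  on the undirected projection (antiparallel weights summed), the
  convention of the source literature for those measures.
* Betweenness is computed on the **directed, unweighted** graph with
  fractional credit for shortest-path multiplicities, raw counts by
  default. Transfer counts measure traffic, not distance, so they do not
  define edge lengths; downstream classification is rank-based, making
  the normalisation choice inert.
* Reciprocity is edge-presence based: the fraction of directed edges
  whose antiparallel counterpart exists. Assortativity is the Pearson
  correlation of degrees over edge ends on the undirected projection; a
  regular graph has zero variance and the coefficient is reported as
  undefined, not zero. Flow hierarchy is the fraction of edges on no
  directed cycle (computed via strongly connected components). Average
  path length defaults to the largest connected component of the
  undirected projection (the small-world reference convention); a
  directed largest-SCC mode is available, since transfer networks can
  have isolated pockets.

## Discrete power-law tail fit

Degrees are counts, so the tail model is the discrete power law
p(k) = k^(−γ) / ζ(γ, k_min) with the Hurwitz-zeta normalisation. γ is
estimated by numerical maximum likelihood (bounded scalar optimisation,
tolerance 1e-8, bounds 1+1e-6 to 25). k_min is chosen by scanning every
distinct sample value up to the 90th percentile — the cap guards
against vanishing tails — keeping at least `min_tail` (default 10)
observations, and minimising the KS distance between the empirical and
fitted tail CDFs evaluated from both sides of each empirical step.

Goodness of fit is a semiparametric bootstrap: each replicate resamples
the body (below k_min) empirically, draws the tail from the fitted
model by exact inverse-CDF sampling (doubling plus bisection on the
zeta-function CDF, no analytic approximation), and is **refitted in
full**; the p-value is the fraction of replicates whose KS distance is
at least the observed one. The 95% CI for γ is a nonparametric
percentile bootstrap, refitted in full per resample. All bootstrap
streams derive from one seed; identical seeds give identical fits. The
calibration tests run at desk scale (tail n = 1000, 200 replicates) and
check a conservative band: at least 60% of true-model replicates with
p ≥ 0.1 and at least 85% CI coverage.

A continuous-approximation fit is deliberately not offered; the
brute-force likelihood grid (step 1e-4) used as the test oracle is the
only alternative estimator in the repository, and it is kept out of the
library path.

## Strength scaling and betweenness quadratic

The scaling s ~ k^β is fitted by OLS of log s on log k over nodes with
k ≥ 1 and s ≥ 1 (at least three distinct degrees required). The mean
edge weight w̄ = Σs/Σk (exactly the mean undirected edge weight) is
reported so the uncorrelated baseline s = w̄·k can be drawn; β > 1 means
well-connected wards carry disproportionately more traffic.

Betweenness versus degree is fitted by least squares to
b ~ c0 + c1·k + c2·k², the shape expected of randomised networks. Nodes
beyond ±2 (configurable) internally studentised residuals — residuals
scaled by the fit's residual SD and the hat-matrix leverage — are
flagged "high" (structurally more important than their connectivity
predicts) or "low". The threshold is configurable because "significant"
outlyingness in this context has no canonical criterion; ±2 is the
usual studentised-residual rule of thumb.

## Small-world coefficients

σ = (C/C_random)/(L/L_random) and ω = L_random/L − C/C_lattice, with C
global transitivity and L the average path length, all on the
undirected, unweighted projection of the largest connected component.
σ ≫ 1 indicates small-worldness; ω is near 0 for small worlds, near −1
for lattices, near +1 for random graphs. (Some applied papers read
σ ∈ [0, 1] with values near 1 as small-world; that reading is
inconsistent with the coefficient's definition and is not adopted
here.)

Random references are degree-preserving double-edge swaps
(`rewiring_per_edge × |E|` attempted swaps, default 10) that reject
disconnecting moves via windowed connectivity checks. Complete graphs
cannot be altered by any valid swap and are returned as-is. Lattice
references use a greedy, annealing-free latticization: nodes are placed
on a ring (numeric labels in numeric order, so ring-labelled graphs
latticize onto their own ring), edges are visited longest-first, and
for each edge up to 40 random partner edges are examined, applying the
swap pairing that strictly reduces total circular edge length. The
procedure stops when a full sweep accepts nothing (or after 100
sweeps). A ring lattice is a fixed point of this procedure, and on
Watts–Strogatz graphs it recovers near-ideal lattice clustering (e.g.
C_lattice ≈ 0.64 against the k = 10 ring ideal of 2/3). Both reference
families preserve the degree sequence exactly, which the tests assert
as multiset equality. Defaults n_refs = 10, rewiring_per_edge = 10;
both surfaced as parameters.

## Hub/bottleneck classification

Hubs are nodes with degree at or above the empirical 80th percentile of
degrees; bottlenecks likewise on betweenness; the four-way category is
the conjunction. Ties at the threshold are included, the quantile is
configurable, and the cut is rank-based (invariant to order-preserving
transforms). Degree is the default hub metric; strength is available as
a sensitivity flag. When degrees are (nearly) constant — which happens
when a dense simulation saturates the network — the cut degenerates to
all-or-nothing and a warning is attached, but a classification is still
emitted.

## The synthetic-data generator

The generator emulates the structural features the analysis assumes,
not the clinical realism of any particular hospital:

* admissions enter at one emergency node and move by a row-stochastic
  routing matrix with an absorbing DISCHARGE state (5% direct discharge
  from the entry node, 30% per ward step — a geometric journey length
  of ~4 moves, in the range of acute admissions);
* the routing graph is structurally sparse, as real location graphs
  are: ordinary wards share a small symmetric neighbourhood (2–8
  corridors, used in both directions), designated hubs exchange with
  every location, and the emergency entry triages broadly but one-way —
  a pure "distributor" in the net-connectivity sense. This yields the
  degree spread, high reciprocity (~0.9) and negative assortativity the
  analysis assumes, instead of the near-complete graph that uniform
  routing produces at realistic admission counts;
* a designated fraction of wards receives ~8× the baseline routing
  attractiveness and is reachable from everywhere, giving them inbound
  probability mass at least 3× the median non-hub ward — the planted
  ground truth for hub recovery;
* investigation round-trips (ward → radiology → ward) arise naturally
  from routing mass into and out of hub locations; no special
  mechanism exists;
* stays are exponential per location (entry 2–8 h, wards 4–72 h). The
  analysis uses only event ordering, so the duration law is inert.
* a hard cap of 200 events per admission raises a clear error on
  near-non-absorbing routing; validation rejects configurations whose
  discharge state is unreachable before any simulation runs.

The random stream is split per admission from one seed, so a log is
byte-reproducible and extending `n_admissions` never reshuffles earlier
journeys. Optional defect injection (missing exit timestamps, duplicate
rows) exercises the ingest validation from a separate substream.

What passing tests on this generator do **not** show: real extracts
have richer defects (clock skew, retrospective corrections, ward
renamings), genuinely heavy-tailed degree distributions over hundreds
of locations, and length-of-stay and capacity dynamics the Markov model
ignores. Desk-scale simulations (tens of wards, hundreds to thousands
of admissions) also saturate toward dense networks faster than a real
hospital's location graph, which compresses the degree distribution;
the power-law machinery is therefore validated separately on exact
draws from its own model. Queueing/bed-capacity dynamics, seasonal
effects and time-resolved (dynamic) networks are out of scope.

## Problem sizes and defaults

The shipped analysis (`analysis/01…03`) simulates 40 locations, 8 care
categories, 4 designated hubs and 4,000 admissions at seed 42 —
roughly a quarter of the admission count of a multi-year single-centre
extract, chosen as a desk-scale cohort with stable network statistics.
Bootstrap replicates default to 1000 in the library and are reduced in
the scripted analyses (200–300) where the CI/p-value precision they buy
is not needed. Reference counts default to 10.

## Known limitations

* The routing matrix is time-homogeneous; no strain response, seasonal
  or diurnal structure.
* Betweenness uses unweighted shortest paths; weighted (traffic-aware)
  centralities are out of scope.
* The latticization is a greedy local optimum; its clustering
  ceiling is slightly below the theoretical ring-lattice maximum, which
  biases ω upward by a few hundredths on strongly clustered graphs.
* The GOF p-value is a plain bootstrap fraction (no +1 correction); at
  B = 200 its resolution is 0.005.
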