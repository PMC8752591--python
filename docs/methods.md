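# Methods

## The Vicsek model

`flockgn.vicsek` simulates N point particles moving at a common speed v on an
L x L square with periodic boundary conditions. The state of particle i is a
position (x_i, y_i) in [0, L)^2 and a heading theta_i in [-pi, pi). One
synchronous step performs, for every particle simultaneously from the time-t
state:

1. position update with the *current* heading (the backward-update variant,
   matching the printed update equations of the original model):
   x_i(t+1) = x_i(t) + v cos(theta_i(t)) dt, likewise for y, wrapped into
   [0, L);
2. heading update theta_i(t+1) = <theta_i(t)>_r + dtheta, where
   <theta>_r is the direction of the summed heading unit vectors over all
   particles within periodic distance < r of particle i (particle i
   included), and dtheta is uniform on [-eta/2, eta/2].

The circular mean is computed with the two-argument arctangent of
(sum sin, sum cos); a plain arctangent of the ratio loses the quadrant. The
measure-zero case of an exactly cancelled unit-vector sum (detected at
resultant length <= 1e-9, the float-rounding scale of the sum) returns
heading 0 and is counted on the trajectory.

Neighbor search uses `scipy.spatial.cKDTree` with `boxsize=L` (a periodic
k-d tree); pairs at distance exactly r are filtered out to keep the strict
`distance < r` convention. The simulator is validated against an O(N^2)
all-pairs oracle in the test suite. `radius > L/2` is rejected because the
minimum-image convention would be ambiguous.

Defaults follow the study conditions: v = 0.03, r = 1, dt = 1; the
full-scale system is N = 4000 in a box of side L = 31.6 (density
rho = N/L^2 ~ 4).

### Alignment order parameter

v_a = |sum_i v_i| / (N v), the length of the mean heading unit vector: 1 for
perfect alignment, ~0 for disordered motion. It is recorded at every step.

### Steady state

Run lengths are "until steady state" with a hard cap (`n_steps`). The
steadiness rule: after a burn-in of 10 windows, stop when the 50-step
running mean of v_a changes by less than 1e-3 across 3 consecutive window
comparisons. A single window comparison proved unreliable: at N = 4000,
eta = 3.5 the early transient has a long plateau in which one comparison is
flat by chance while the system is still ordering, which biases the steady
value low. The trailing statistic is the mean of v_a over the final 50
steps.

The detector is an efficiency device for dataset builds. Quantitative
steady-state *measurements* run to the full step cap instead: at low noise
v_a keeps creeping upward at under the detector's resolution (~2e-5 per
step), so stopping on the detector biases the trailing mean low by several
hundredths.

At high noise v_a never settles to a narrow band — it wanders with large
amplitude around its long-time mean — so high-noise runs typically run to
the cap and the seed-to-seed spread of the trailing mean is large (roughly
0.03 to 0.35 at eta = 3.5); quantitative statements average over several
seeds.

## The cluster order parameter k

A configuration is summarized by the feature list [x, y, v_x, v_y] per
particle (raw box coordinates, velocity components v cos theta, v sin
theta; no standardization, and no periodic unwrapping of coordinates). For
each candidate k in [2, floor(sqrt(n))] the features are clustered by
k-means (scikit-learn; k-means++ seeding, 10 restarts, seeded) and the
partition is scored by the average contour coefficient

    S_i = (b_i - a_i) / max(a_i, b_i),      S = mean_i S_i,

with a_i the mean Euclidean distance from sample i to the other members of
its own cluster (S_i = 0 for singletons) and b_i the mean Euclidean distance
to the members of the nearest foreign cluster. The nearest foreign cluster
is selected by the mean *squared* distance while b_i itself is the plain
mean distance; the two conventions coincide for well-separated clusters but
can differ in general, and both roles are kept as defined. The k maximizing
S is the cluster order parameter; ties break toward the smaller k
(parsimony). A brute-force O(n^2) oracle and, where the nearest-cluster
conventions agree, scikit-learn's `silhouette_samples` back the
implementation in tests.

Two caveats are deliberate fidelity choices rather than oversights:

* with v = 0.03 and L of order 10, position dominates the Euclidean metric,
  so k mostly measures spatial fragmentation; standardizing the features
  changes the statistic (we measured it, see "Scaled-down sweeps") and is
  not applied;
* clusters straddling the periodic boundary can be over-counted because the
  features use raw coordinates.

### Timescales

v_a equilibrates on the local-alignment timescale, but the spatial cluster
structure coarsens on the much longer box-crossing timescale L/(v dt)
(co-moving flocks must meet to merge). Sweeps that report k therefore run
to the full step cap rather than stopping on v_a-steadiness, and steady k
is averaged over a small number of trailing snapshots (default 1-3) rather
than the 50-step window used for v_a — an optimal-k search per snapshot
costs ~sqrt(n) k-means fits and k varies little within the trailing window.

### Scaled-down sweeps

The phase-transition trend checks run at reduced scale: the noise sweep at
N = 500, rho = 4 (grid eta in {0.1, 1.5, 2.5, 3.5, 5}), the density sweep
at L = 10, eta = 2 with rho in {0.25, 1, 8} varied through N, 10 seeds per
grid point and a 2500-step cap (about seven box crossings, enough for the
cluster structure to coarsen). Trends are
assessed by the Spearman rank correlation over per-run values with p < 0.05.
At this scale v_a falls with noise and rises with density, and k rises with
noise, all strongly. The mirror trend — k falling with density — does *not*
emerge at this scale: measured Spearman rho ~ 0 (p ~ 0.8). Two structural
reasons: varying density through N ties the search bound k <= sqrt(n) to
the grid point, strangling k exactly where it should be large (sparse
systems), and both the sparse disordered gas and the dense ordered flock
have nearly uniform spatial density, which the position-dominated metric
cannot distinguish. Standardizing the features does not recover the trend
either (measured Spearman rho ~ +0.3, wrong sign). The corresponding
acceptance check is left failing rather than weakened.

## CDGNet

`flockgn.graph` turns a configuration into an attributed graph G = (u, V, E):
one node per particle with attribute (cos theta, sin theta) (the heading
encoded without the +/-pi seam), a pair of directed edges for every neighbor
pair (periodic distance < r, strict; no self-loops) carrying the scalar
periodic distance, and a global input (0, t/n_steps) — a zero placeholder
plus the normalized snapshot time. The supervised target (v_a or k at the
snapshot time) is never part of the input. Because the input graph only
contains headings and relative distances, predictions are exactly invariant
under particle relabeling and rigid periodic translations.

`flockgn.gnet` implements encode-process-decode in numpy with explicit
reverse-mode gradients (verified against central finite differences to
~1e-8 relative in the tests):

* **encode**: independent linear maps lift node, edge, and global attributes
  to `hidden`-dimensional latents (default 64);
* **process**: a graph-network block applied `n_rounds` times (default 7,
  enough hops to cross the interaction graph of the full-scale box) with
  weights shared across rounds. Within a block, synchronously: every edge is
  updated from (e_k, v_receiver, v_sender, u) by the edge MLP; incoming
  updated edges are mean-aggregated per node; every node is updated from
  (mean edge, v_i, u) by the node MLP; updated edges and nodes are
  mean-aggregated per graph; the global is updated from (mean edge, mean
  node, u) by the global MLP. Aggregations are arithmetic means (robust to
  particle number across densities; empty aggregations give zero vectors).
  Update MLPs have two tanh hidden layers (default 64 wide) and a linear
  output;
* **decode**: an MLP maps the final global latent to a scalar, squashed by a
  logistic to [0, 1]. In v_a mode that is the prediction; in k mode the
  output is rescaled by k_scale = sqrt(N), the search bound of k, which also
  normalizes k targets during training.

**Residual processor updates.** Each block output adds the previous latent
(e' = e + MLP(...), likewise nodes and global). Without the skip, a
shared-weight tanh block iterated 7 times contracts the latents toward an
input-independent fixed point: in our experiments training then stalls
exactly at the target-variance loss (the mean predictor) for any
n_rounds >= 3, while n_rounds = 1 trains fine. The skip leaves the update
functions' inputs and the information flow unchanged and is the standard
processor form in encode-process-decode architectures. It can be disabled
(`residual=False`).

Training minimizes mean squared error by mini-batch stochastic gradient
descent (plain SGD by default, learning rate 1e-3, batch 16; an
adaptive-moment variant is available and used in the bundled experiments
because it converges in far fewer epochs on CPU). All randomness is seeded;
the best-validation weights are returned; a non-finite loss aborts with a
diagnostic.

## Datasets

`flockgn.data` builds (configuration, order parameter) datasets by the study
protocol: per noise point, independent runs from disjoint train/test seed
pools (disjoint by parity of the derived seed), each run to steady state
under the cap; a fixed number of snapshots is sampled evenly over each run
(always including the final step) and stored with its step index, total run
length, v_a, and optionally k with the exact seed used to compute it — so
every stored target is recomputable from its stored configuration. The
full-scale manifest is N = 4000, rho = 4, v = 0.03, noise grid
{0.1, 1.5, 2.5, 3.5, 5}, 100 train + 100 test runs per noise point.
`fixture_manifest` provides the reduced version used by the tests (default
N = 100 at the same density).

Augmentation is restricted to exact symmetries of the periodic square —
periodic translations, quarter-turn rotations (positions and headings
rotated together), and reflection — each of which preserves v_a, all
pairwise periodic distances, and hence the cluster structure, to floating
point rounding.

What the fixtures do not emulate: the full-scale runs have 40x more
particles, so per-snapshot k can span its much larger sqrt(N) = 63 search
range, and statistical dispersion of all quantities is larger at fixture
scale. Passing fixture-scale learning checks shows the architecture and
optimization work end to end, not that full-scale prediction accuracy is
reproduced (the original training configuration is unpublished).

The learning-sanity experiment uses N = 100 at rho = 4, eta in {0.1, 3.5},
20 training and 10 validation runs per noise point, a 1500-step cap (about
nine box crossings, so the cluster structure equilibrates), and 4 snapshots
per run. At this scale the k target is dominated by the silhouette-argmax
jitter of small systems: a feature-regression oracle (edge counts, mean
edge distance, connected components, v_a, time) explains only ~12% of its
variance, so beating the mean predictor on k is possible but by modest
margins, while v_a is learned to an order of magnitude below the baseline.

## Numerical and interface choices

* Angles live in [-pi, pi) everywhere; angle comparisons in tests are
  modulo 2 pi (the +/-pi seam maps to -pi).
* Positions are box-absolute in [0, L); one convention everywhere.
* Configuration CSVs (`x,y,theta`) use shortest round-trip float
  representation and read back bit-identically.
* Trajectory and dataset containers are NPZ archives with an embedded JSON
  manifest; model checkpoints store flat weight arrays plus a JSON
  hyperparameter block.
* All commands and library entry points take a single seed from which every
  stream of randomness is derived; identical seeds give bit-identical
  trajectories, datasets, and training curves.

## Known limitations

* The cluster order parameter inherits the silhouette statistic's
  instability on near-uniform data: at small n its argmax jitters by several
  units between seeds.
* The density trend of k is not reproduced at reduced scale (see above).
* Plain SGD needs many more epochs than the adaptive-moment option at these
  problem sizes; the defaults favor fidelity, the experiments favor CPU
  budget.
* Full-scale (N = 4000) k computation costs ~sqrt(N) k-means fits over a
  16M-entry distance matrix per snapshot; dataset builds at that scale
  should sample k sparsely.
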