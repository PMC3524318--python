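# Methods

## Preprocessing

Raw probe intensities pass through four stages. Duplicate probes of a
gene are collapsed by per-time-point arithmetic mean. Genes whose
coefficient of variation across time (sample sd / mean, on the raw
intensity scale) is at or below 0.15 are dropped as not differentially
expressed; the comparison is strict (`>` keeps), so a gene exactly at
the threshold is removed. Intensities are then converted to log
concentration ratios, LCR(t) = ln(C_t / C_0); the natural log is a free
choice because the final per-time-point standardization absorbs any
positive per-column rescaling, and a test verifies that base-e and
base-2 pipelines give identical downstream ΔLL values to 1e−9. The
standardization z-scores each time-point column across genes; columns
with zero spread — in particular the all-zero baseline column at t = 0,
where a z-score is undefined and zero is the semantically correct
LCR — are left unchanged.

## Spline parametrization

The fitted curve is a piecewise cubic on [t_min, t_max] with two
interior knots placed at sample quantiles of the sampling times
(probabilities 1/3 and 2/3; linear-interpolation definition, index
h = 1 + (n−1)p). On the canonical 12-point grid this puts the knots at
16/3 ≈ 5.333 h and 52/3 ≈ 17.333 h, which also delimit "early" and
"late" response windows.

Of the 12 raw coefficients (4 per piece), 8 linear constraints are
imposed: C0/C1/C2 continuity at each knot and the natural boundary
conditions f″(t_min) = f″(t_max) = 0. The constraint matrix has rank 8,
leaving 4 free parameters; we take the middle piece's coefficients
β₂ as free. Each outer piece is then a fixed linear image of β₂
(a 4 × 4 transfer matrix obtained by solving the four equations pinning
that piece), so fitting reduces to OLS of y on an n × 4 reduced design
whose middle-region rows are exactly (1, t, t², t³) and whose
outer-region rows are (1, t, t², t³) composed with the transfer matrix.
Region membership uses half-open intervals ([t_min, K1), [K1, K2),
[K2, t_max]); continuity makes the boundary assignment value-irrelevant
but it is fixed for bookkeeping. The fit is validated against an
independent derivation — OLS over an orthonormal nullspace basis of the
constraint system — to 1e−6, and the fitted coefficients are checked to
satisfy all constraints to 1e−8.

The residual variance is the MLE σ̂² = RSS/n (not RSS/(n−4)): the
log-likelihood −(n/2)(log 2πσ̂² + 1) is maximized jointly over
coefficients and variance, and the pairwise time-order comparison uses
the same convention on both sides so the two compared models are
identically formed. An exact fit (RSS/n below 1e−12) is reported as a
+∞ log-likelihood sentinel; this arises only on noiseless synthetic
data, and two exact fits compare as a tie.

## Time-order scoring

Each gene's cumulative curve F(t) is the closed-form piecewise
antiderivative of its fitted spline with F(t_min) = 0 and continuity
constants C1 = ∫ f over [t_min, K1] and C2 = C1 + ∫ f over [K1, K2].
For a pair (a, b), both orderings are scored on the *shared* predictor
block X = (1, F_a, F_b): the ordering a → b gets the log-likelihood of
regressing y_b on X, b → a that of regressing y_a on X, each at MLE
variance RSS/n. Their difference ΔLL is antisymmetric by construction
and its sign gives the inferred direction; its magnitude is the edge
weight. No significance cutoff is applied to a single ΔLL — pruning is
the network layer's job.

The two regressions have different response variables, so the
comparison is only meaningful when the responses are on comparable
scales; the per-time-point standardization upstream provides this in
the pipeline. The simulation benchmark applies the pair-level analog
(each response scaled to unit sample sd) for the same reason: a
downstream gene that integrates its driver grows to a much larger raw
amplitude, and without variance unification the comparison measures
scale, not fit.

Responses are the observed standardized LCRs (not the spline-smoothed
values): the regression's error term then carries the measurement
noise, which is what the likelihood comparison should weigh.

## Network construction

Per pair, only the positive-ΔLL direction is kept as a directed edge;
an exact tie (measure zero in practice) contributes no edge. Small
networks are pruned by removing edges below a quantile (default: the
median) of the kept positive weights — the zeroed mirror entries are
bookkeeping, not evidence, and are excluded from the distribution.
Redundant edges are then removed by transitive reduction: an edge
(u, v) is deleted iff v stays reachable from u through a path of
length ≥ 2 with (u, v) removed, evaluated against the thresholded
graph (not iteratively), which on a DAG yields the unique minimal
reachability-preserving subgraph. Directed cycles, should thresholding
leave any, are kept intact and flagged with a warning.

Genome-scale networks are skeletonized by a maximum-weight spanning
tree computed with a hand-written Prim's algorithm on symmetrized
weights (the pair's positive ΔLL, the strength of the ordering
evidence irrespective of direction); each selected edge keeps its
original direction, disconnected inputs yield a forest, and weight
ties break lexicographically on the sorted node pair for
reproducibility.

Incoming-edge hubs are nodes with out-degree 0 and in-degree ≥ 1,
ranked by in-degree (ties alphabetically). Each hub's trend is the
sign of its mean fitted LCR over the late window [K2, t_max]
(computed exactly from the cumulative curve); an exactly zero mean is
reported as the underexpressed boundary case with an explicit flag.

## Synthetic data generator

The generator emulates a stimulation time course on the canonical
12-point grid. Gene trajectories are logistic onset ramps (amplitude
0.8–1.6 with random sign, steepness 0.4–0.9 h⁻¹), shifted so the LCR
is exactly 0 at t = 0. Coupled pairs follow the forward model
df_b/dt = k1 f_a + k2 f_b with f_b(0) = 0, integrated by a
high-accuracy adaptive solver (rtol 1e−10) and verified against the
closed form for exponential inputs; gains default to k1 ∈ [0.3, 1]
(upstream drive) and k2 ∈ [−0.3, 0] (decay). Observation noise is
i.i.d. Gaussian on the LCR scale, default sd 0.05 — small relative to
the unit-scale curves, as for strongly responding genes on arrays.

Cascades draw onset lags in two waves consistent with the early/late
response definitions: early onsets in [1, 4] h (so the response
precedes the first knot) and late onsets in [17.33, 24] h, with 40% of
genes early by default. Each gene after the first additionally
integrates its predecessor through the coupling ODE; because the ODE
is linear, the upstream curve is normalized and the coupled component
rescaled (peak 0.2–0.5) — equivalent to choosing an effective k1 —
which keeps amplitudes O(1) along the chain and keeps each gene's
curve dominated by its own onset, as in real response profiles. A
`own_ramp=False` mode instead makes every downstream gene purely the
integrated response of its predecessor; in that pure chain the
integrated regression relation holds exactly, which the zero-noise
self-consistency test exploits. Cascade tables are emitted directly on
the standardized-LCR scale (each gene scaled to unit sample sd); a
`standardize=False` mode returns plain LCRs for exercising the
preprocessing path.

What the generator does *not* emulate: array-specific noise (dye bias,
saturation, intensity-dependent variance), missing values, probe-level
replication structure, and regulatory topologies beyond a single
chain with two waves. Passing recovery tests therefore show that the
method identifies time order when its generative assumptions
(smooth ramp-like curves, linear coupling, additive Gaussian noise)
approximately hold — not that it is robust to violations of them.

A quantile-threshold t-test screen is included as the baseline
comparator: per gene, one-sample t-tests of the LCR values against 0
over an early and a late window; a gene is kept when its early p-value
exceeds the 0.6 quantile of the early p-value distribution across
genes and its late p-value falls below the 0.05 quantile of the late
p-values. Note these thresholds are quantiles of the *empirical*
p-value distributions, not fixed significance levels — an unusual
construction kept as such; its behaviour therefore depends on the
cohort composition.

## Numerical choices and degenerate inputs

* Quantiles (knots, network thresholds) use the linear-interpolation
  sample quantile throughout.
* Rank checks guard the spline design (must be 4) and the pairwise
  design (collinear cumulative curves raise an informative error).
* Perfect fits are +∞ sentinels; ∞ − ∞ ties resolve to ΔLL = 0.
* The spanning tree and hub ordering are fully deterministic
  (lexicographic tie-breaks), and pipeline runs with identical config
  and input are byte-identical.
* Problem sizes in the test suite: the constrained-fit equivalence is
  checked on 50 random genes, continuity on 100 random fits, direction
  recovery on 500 simulated pairs, the spanning-tree and reduction
  oracles on graphs of up to 10 nodes, the end-to-end run at 200 genes
  (19,900 pairs), and the late-wave hub-recovery experiment over 100
  seeds at 12 genes — sizes chosen so the whole suite completes in a
  few minutes on one CPU while exercising every scale the method
  targets short of a full genome.

## Known limitations

* The ΔLL comparison has different response variables on its two
  sides; it is scale-sensitive by construction and meaningful only
  after variance unification. Genes with intrinsically smoother
  trajectories attract incoming edges somewhat independently of true
  order — on two-wave cascades this shows up as near-random ordering
  *within* a wave while the early→late cross-wave direction is
  recovered reliably.
* No p-value or FDR accompanies ΔLL; edge pruning is purely
  rank-based.
* The spline has fixed knots and 4 free parameters: trajectories with
  more than two regime changes are underfit, inflating that gene's
  residual variance and biasing its edges outward.
* Time-lag magnitudes are not estimated — only the order.
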