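# Methods

This note documents the models, conventions and design choices behind
`richclub-control`, in the order the pipeline uses them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Linear dynamics and stabilization

Regional activity is modeled as `dx/dt = S x + B u` with
`S = A/(1 + λ_max(A)) − I`. Dividing the connectome `A` by one plus its
spectral radius and subtracting the identity places every eigenvalue of `S`
in `[λ_min/(1+λ_max) − 1, λ_max/(1+λ_max) − 1] ⊂ (−2, 0)`, so the
uncontrolled system decays to the origin. This is the standard normalization
of the optimal-control literature this package follows; it is a modeling
convention, not an estimate, and is the main reason all energies are
dimensionless.

Assumptions inherited from the framework: linearity of the dynamics,
time-invariant coupling, noiseless evolution, and the identification of
"brain states" with fixed activation vectors. None of these hold exactly for
real neural dynamics; the framework is a first-order probe of how network
*structure* constrains steering effort.

## Optimal control solver

Cost `J = ∫ (xT − x)ᵀ(xT − x) + ρ uᵀu dt` with hard endpoints. The
Pontryagin conditions give the linear state/costate system
`d/dt [x; p] = M [x; p] + [0; 2 xT]` with
`M = [[S, −BBᵀ/2ρ], [−2I, −Sᵀ]]` and `u* = −Bᵀp/2ρ`. The solver:

1. folds the constant forcing into an augmented `(2N+1)` matrix and takes a
   single matrix exponential over the horizon;
2. solves the linear system mapping the unknown initial costate `p0` to the
   endpoint; if the reciprocal condition of that map is below `1e-12`, the
   control set cannot steer every direction. The solver then falls back to
   the minimum-norm least-squares solution and lets the endpoint check
   decide: a singular-but-consistent problem (e.g., an uncontrolled,
   decoupled coordinate that starts and ends at equilibrium) is legitimately
   solvable, while an inconsistent one raises an
   `UncontrollableSetError` naming the control-set size;
3. propagates state and costate on the time grid by iterating the one-step
   matrix exponential (exact per step, no integration error), and rejects
   any solution whose relative endpoint error exceeds `1e-4`.

**Energy normalization.** Per-node energy is `∫ uᵢ(t)² dt` (trapezoid rule)
divided by the number of *reference* timesteps the horizon comprises,
`T / dt_ref` with `dt_ref = 1e-3`. At the defaults (`T = 1`,
`n_steps = 1000`) this equals dividing by `n_steps`; unlike a literal
division by the grid size it is invariant to grid refinement (asserted to 1%
in the tests) and comparable across horizons, which is the purpose of the
normalization. Mean energy averages over **all** N regions, including
non-controllers, whose contribution is identically zero.

**Stability** is `1 / energy(x → x)`. The zero state (or any maintenance
energy below `1e-12`) returns the sentinel `inf`: the origin is the stable
equilibrium and needs no input.

**State-cost weighting** is the identity; `ρ` (default 1) and `T` (default
1) are exposed everywhere; `n_steps` defaults to 1000.

Restricted control sets use the diagonal `BBᵀ` of the node mask; this is
algebraically identical to a reduced selection matrix and keeps every
operation a fixed-size dense linear-algebra call.

Verification is dual-route throughout: a scipy collocation (`solve_bvp`)
oracle on the scalar problem, and an independent RK4 replay of the returned
control signal on random instances. The replay oracle is restricted to
well-conditioned instances (≥ 60% controllers, bounded control amplitude);
near-singular control sets produce controls of magnitude 10³–10⁴ whose
linear interpolation between grid points dominates the replay error, and
those regimes are exercised instead through the error path above.

## Rich-club detection

`φʷ(k)` = (summed weight among nodes of degree > k) / (sum of the equally
many strongest weights network-wide), computed for k = 1..max degree and
undefined (NaN) where no edges survive. Because degree-preserving rewiring
fixes the degree sequence, a single sort of edges by the smaller endpoint
degree yields the whole curve in O(E log E), and the null ensemble reuses
the same edge machinery.

Nulls are Maslov–Sneppen double-edge swaps, 10 attempted swaps per edge by
default, weights riding with their edge slots — degree sequence and weight
multiset are preserved exactly (asserted per call in tests). The kernel is
JIT-compiled with numba when available, with an identical pure-Python
fallback.

Per level, the one-sided exceedance p-value is the fraction of null curves
at or above the empirical value; the significant regime is `p < α`
(default 0.05), per-level, uncorrected, with no contiguity requirement.
`k_maxΦ` maximizes `Φ` inside that regime, ties to the smallest k. Club
membership is degree **strictly greater** than `k_maxΦ`.

Group-level club: the group size is round-half-away-from-zero of (mean
individual membership fraction × N) — e.g. a 10.10% mean fraction on a
219-region parcellation gives 22 regions — and members are the nodes most
frequently assigned across individuals. Deterministic tie-breaks: frequency
ties by higher mean degree, then lower node index; the fixed-size top-degree
variant breaks degree ties by strength, then node index. Desk-scale default
is 200 nulls per curve (configurable upward); the acceptance checks run at
100.

## Spin nulls and matched reference sets

Parcels are represented by their unit-sphere centroids. Each permutation
draws one uniform random 3D rotation, applies it to left-hemisphere
centroids and its sagittal mirror conjugate (`M R M`, `M = diag(−1,1,1)`) to
right-hemisphere centroids, and matches rotated to original positions
greedily (globally closest pair first, remove both, repeat), guaranteeing a
hemisphere-preserving bijection. Parcel contiguity, which vertex-level
rotation methods preserve, is not representable at centroid level; the
rigid rotation preserves the spatial autocorrelation structure that matters
for the null.

Matched reference sets draw `n_candidates` (default 500) random size-matched
sets and return the one whose criterion — mean pairwise connectivity-profile
correlation, or summed within-set weight — is closest to the target's; first
sampled minimum wins ties. Whether such sets should additionally be
spin-constrained is not determined by the procedure being emulated; free
random draws filtered by criterion are used.

Permutation p-values count ties as exceedances and use the plain plug-in
fraction (zero is attainable), with `two-sided` as twice the smaller tail
capped at 1.

## Inference

The repeated-measures comparison of rich-club-excluded vs. reference-
excluded metrics with the mean activation difference as covariate is
realized as OLS of the paired difference on the centered covariate; the
intercept F-test (df 1, n−2) is the condition effect. With two within-
subject levels this is algebraically the covariate-adjusted paired
comparison. A covariate without variance (stability measures: initial =
target state, difference ≡ 0) is dropped rather than left to produce a
singular design. The covariate enters *signed*; an absolute-value variant is
a caller-side transform. The per-subject reference value is the mean of the
metric over all reference sets, treated as the second repeated measurement.

Post hoc direction confirmation uses one-tailed paired t-tests; effect sizes
are paired Cohen's d (mean difference over SD of differences; a zero-variance
difference returns a signed infinite sentinel).

Lesion-scan ranks: impact = energy increase (energy measure) or stability
decrease (stability measure) upon removing a region from the control set;
rank 1 = largest impact; ties resolve by node index; regions whose lesion
fails rank last with a warning. Mean rank averages over tasks × measures.
Set-, map- and network-level inference permutes the relevant quantity
through the spin ensemble.

## Graph descriptors

Participation coefficient is strength-based by default (`use_binary=True`
for the edge-count variant) since the pairing of structural edges with
functional modules does not prescribe binarization. Communicability uses the
symmetric strength normalization `expm(D^{-1/2} W D^{-1/2})` with regional
values as off-diagonal row sums (self-communicability excluded); zero-
strength nodes get 0 with a warning. Note a property worth knowing: under
this normalization, increasing a single weight can *decrease* other regions'
communicability (the endpoint strengths grow and deflate their other
normalized entries), so no edge-monotonicity should be assumed; the
normalized form is instead invariant to global weight rescaling, which the
tests assert. The cohort outlier rule scores each subject by the summed
group-prevalence of its present edges and flags scores outside
`[Q1 − 2·IQR, Q3 + 2·IQR]`, quartiles by linear interpolation (type 7).

## Synthetic cohort generator

The generator's job is a cohort with a known ground truth exhibiting the two
properties the analysis needs — a heavy right degree tail with a detectable
rich-club regime, and state pairs with a designed stability asymmetry —
while keeping the planted core *passive* in the control-theoretic sense.

Design (defaults in parentheses):

- **Geometry**: n_nodes (100) centroids on the unit sphere, right hemisphere
  an exact sagittal mirror of the left.
- **Background graph**: edge probability `base_density (0.2) ×
  exp(−distance_decay (1.0) × great-circle distance)`; FA-like uniform
  weights in [0.1, 1.0].
- **Planted core**: core_size (10) random nodes, fully interconnected
  (core_density 1.0), with mildly boosted weights (core_weight_boost 1.2,
  capped at weight_high) and elevated feeder probability to the periphery
  (feeder_boost 1.5 on the distance-decayed rate). Two calibration findings
  shaped these values, both verifiable with the recovery and direction
  tests: (i) *strong* weight boosts backfire — the few edges of 2–3-node
  sub-clubs become the globally strongest weights, so the normalized curve
  peaks beyond the full core and recovery collapses; the density contrast,
  not the weight contrast, should carry the signal. (ii) Without feeder
  boosting, occasional core nodes draw no periphery edges at all, and
  excluding the core as a set strands them behind other excluded nodes,
  making core exclusion explosively costly — real hubs are hubs through
  abundant feeder connectivity.
- **Subjects**: n_subjects (10) variants of one template; a subject_jitter
  (0.1) fraction of weights resampled and half that fraction of edges
  toggled on/off symmetrically; removals that would disconnect a subject are
  reverted. Per-subject seeds are `seed + 1000 × subject_index`.
- **States**: state A is a unit-norm random combination of the
  n_state_modes (5) slowest eigenmodes of `S` plus Gaussian noise
  (state_noise_sd 0.05); state B adds the fastest modes with weight
  state_gap (1.0) before renormalization; both are scaled to equal norm.
  Activation on the planted core is damped by core_activation_damping (0.3)
  in both states. The damping is essential, not cosmetic: the slowest mode
  is the Perron vector and localizes on the dense core, and without damping
  the core carries the state amplitude and becomes the *most* expensive
  exclusion. Empirical task states are quiet on hub regions; the damping is
  the generator's one-parameter version of that fact, and it is what makes
  "passive core" a planted ground truth rather than a hope.
- Disconnected template draws are regenerated (≤ 100 attempts) rather than
  repaired, keeping the generative law clean.

What the generator does **not** emulate: tractography biases and weight-
distance coupling, realistic FA distributions beyond the range, geometric
mesh structure, task-specific activation content, subcortex. Passing tests
therefore show the *machinery* behaves correctly and that the analysis
recovers planted structure under its own assumptions — not that any
particular empirical effect must replicate.

## Problem sizes and determinism

Defaults in tests and the acceptance script are desk-scale by design:
100-node cohorts of 10 subjects, 100–200 rewired nulls per curve (vs. 10⁴ at
study scale), 8–50 spin permutations for network-level comparisons (50 is
the study-scale value), 10³ regional permutations (vs. 10⁴), `n_steps`
300–1000. Every random step takes an explicit seed; identical configuration
and seed reproduce every number bit-for-bit (`RunReport.hash()` asserts
this), and the solver itself contains no randomness.

## Known limitations

- The per-k significance rule (uncorrected, non-contiguous) is one of
  several defensible readings of a "significant rich-club regime"; it is a
  parameter, not a conclusion.
- The repeated-measures model assumes the reference-set mean is an adequate
  summary of the reference distribution (its spread is discarded).
- Greedy centroid matching is not optimal-transport matching; permutations
  are valid bijections but can differ from vertex-level rotation nulls.
- The linear framework cannot express state-dependent or time-varying
  control; "energy" is a structural effort proxy, not a metabolic quantity.
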