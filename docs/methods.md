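# Methods

This note documents the models, the numerical choices, and the boundaries of
what the synthetic benchmark can and cannot show.

## The detection problem

An association network links taxa whose abundance series co-vary. Within an
environmental triplet {v, w, f} (two taxa, one factor, all three edges
present) the microbial edge v–w may exist only because both taxa respond to
f. Four classifiers judge that edge per triplet:

- **Sign pattern.** Flag when `s_vw · s_vf · s_wf > 0`. Exactly four of the
  eight sign combinations have an even number of negative signs and are
  flagged. The rationale: if v and w respond concordantly (or both
  discordantly) to f, a same-direction association between them is expected
  without interaction.
- **Overlap.** Associations carry a time window [b, b+d) (0-based half-open
  sample indices, so the end is unambiguous). The overlap percentage is
  `O = 100 (min(e_vw, e_vf, e_wf) − max(b_vw, b_vf, b_wf)) / (e_vw − b_vw)`,
  unclipped (disjoint windows give negative O). The flag is strict:
  O > threshold, default 60 — O = 60 exactly is *not* flagged.
- **Interaction information.** `II = CMI(v;w|f) − MI(v;w)` in nats, plug-in
  estimates on equal-width discretized vectors. II < 0 means knowing f
  explains away part of the v–w dependence. Because MI does not involve f,
  the significance of II equals that of the CMI: f is permuted uniformly
  (default 1000 times), and with c = #{CMI_perm ≤ CMI_observed} (ties count),
  p = (c+1)/(iterations+1). The flag requires both II < 0 and p ≤ α
  (default 0.05); negativity alone is available via
  `ii_ignore_significance`. No multiple-testing correction is applied across
  triplets — α is per-triplet.
- **Data processing inequality.** If v and w interact only through f, then
  MI(v;w) ≤ min(MI(v;f), MI(w;f)). The flag uses ≤, so ties are flagged.
- **Combination.** Intersection (default): a triplet flags the edge iff all
  selected methods flag it in that same triplet, and any one flagging
  triplet removes the edge. The alternative reading — each method only needs
  to flag the edge in *some* triplet — is available via
  `agree_across_triplets`. `union` and `single` combinations are provided
  for benchmarking. Taxon–factor edges and edges outside every triplet are
  never removed.

## Discretization

Equal-width binning with |B| = ⌊√n⌋ bins:
`v_d = ⌈(v − v_min)·|B| / denom⌉` with denom = v_max when v_min ≥ 0 and
denom = v_max − v_min otherwise. The asymmetric denominator for all-positive
vectors is implemented as stated in the reference formulation; the arguably
intended range denominator is available via `range_denominator=True`.
The minimum value maps to label 0, so up to |B|+1 labels can occur; labels
enter only through equality, so no remapping is done. Constant vectors and
vectors shorter than 4 samples are rejected. Vectors must be complete — no
missing-value handling. Negative plug-in MI/CMI from floating point are
clamped to 0 (tolerance 1e−12).

## Benchmark simulator

`dy/dt = y (b(t) + A y)`, integrated with LSODA (rtol = atol = 1e−6),
sampled at t = 0, 0.5, …, 49.5 (100 samples); tiny negative states are
clipped to 0 at output.

- **Driver.** ε(t) = round(sin(−2πt/12), 3): a 12-month seasonal signal in
  [−1, 1], phase shift T/4.
- **Growth rates.** Each taxon has a Gaussian niche
  `g(t) = gmax² · exp(−(ε_opt − ε(t))²/(2σ²))` with gmax, σ ~ U(0.3, 1) and
  ε_opt ~ U(−1, 1). The squared amplitude is implemented as stated (it may
  be a transcription slip for plain gmax; `gmax_squared=False` switches).
- **Interaction matrix.** Undirected topology from the Klemm-Eguíluz growth
  process (clique size 5, rewiring probability 0.1 — the algorithm's free
  parameters, chosen once as conventional values), subsampled/augmented to
  round(0.01 · C(n,2)) edges. Each edge receives two directed coefficients
  with magnitude U(0.2, 0.8) (mirroring the stated environmental coupling
  ranges; magnitudes for microbe–microbe links are otherwise unspecified),
  30% of coefficients positive; diagonals −0.5 (self-limitation / carrying
  capacity).
- **Mutualism damping.** A double-positive pair with a_ij·a_ji ≥ a_ii·a_jj
  makes the two-species subsystem diverge in finite time; such pairs are
  rescaled so the product stays below 0.9·diagonal². Without this, roughly a
  third of default-parameter replicates blow up. This is the package's
  stabilization choice; longer positive feedback cycles remain possible but
  are rare at density 0.01.
- **Internal factor.** A second, "internal" environmental factor is an extra
  gLV state: its growth rate uses the same niche function with gmax 0.8,
  ε_opt 0.5, σ 0.5; initial value 0.001; its column couples it into a random
  half of the taxa positively and the rest negatively (magnitudes
  U(0.2, 0.8)); its row is zero off-diagonal (no feedback from microbes) and
  its diagonal is −0.5 like all states, keeping it bounded.
- **Initial abundances.** A randomized broken-stick partition of 1 (uniform
  break of the remaining stick, remainder to the last piece): uneven,
  strictly positive, sums to 1.
- **Noise.** Optional Poisson resampling, cell → Poisson(scale·value)/scale.
  The default scale 1 draws at the abundance value itself; for count-like
  data a scale near the intended total count is more realistic (relative
  abundances < 1 would otherwise mostly collapse to 0).
- **Ground truth.** The unordered taxon pairs with a nonzero off-diagonal
  coefficient in either direction.

## Network construction (stand-in)

The original analysis used eLSA; this package deliberately ships a
simplified zero-delay local-similarity constructor instead, so benchmark
edge counts are not comparable to published medians. Series are standardized
by median and unscaled MAD (zero-MAD series are dropped with a warning). The
pair score is `max over contiguous windows |Σ x_t y_t| / n`, with ties
broken by earliest start then longest duration; the maximizing window
becomes the edge's association window.

The score times n equals the *range* of the prefix-sum random walk of the
products. Under the permutation null that walk's normalized range converges
to the range of Brownian motion, whose tail is Feller's series
`P(R ≥ x) = 8 Σ_{k≥1} (−1)^{k−1} k Φc(kx)`. The default p-value normalizes
by the null step scale `sqrt(E[x²]E[y²] − (x̄ȳ)²)` (drift neglected — robust
standardization keeps means near 0) and applies this tail. A pure
permutation p-value `(#{score_perm ≥ score_obs}+1)/(P+1)` is available
(`p_method="permutation"`), but its floor 1/(P+1) cannot survive a
Bonferroni filter at q ≤ 0.001 once more than a couple of pairs are tested,
so the continuous theoretical p is the default. Edges are kept when
p ≤ 0.001 and Bonferroni q = min(1, m·p) ≤ 0.001 over all m tested pairs;
factor–factor pairs are never tested.

## Evaluation

Positives are false associations; the positive call is removal. TP/FP/TN/FN
partition the microbial edges; TPR = TP/P, TNR = TN/N, FPR = 1−TNR,
PPV = TP/(TP+FP), ACC = (TP+TN)/(P+N). Undefined ratios (e.g. PPV with
nothing removed) are reported as NaN, never 0 or 1. The random-removal model
is multivariate hypergeometric,
`P(k_neg, k_pos) = C(N_neg,k_neg)·C(N_pos,k_pos)/C(N,n)`, computed in
log-space; the tail probability sums log-pmfs with logsumexp.

The benchmark driver evaluates all four methods once per triplet and derives
every removal set (each single method, the intersection) from the same
flags, so per-replicate subset relations are exact by construction of the
combination logic, not an artifact of seeds. Summaries report per-approach
medians and standard deviations.

## Problem sizes and determinism

Defaults are the study conditions: 50 taxa, 100 samples, interaction
probability 0.01, OL threshold 60, II α 0.05 with 1000 iterations, network
thresholds p = q = 0.001. The test suite's replicated benchmark uses 50
replicates at these defaults; the acceptance script uses 12 replicates —
both are the package's own choices of replication for a desk-scale check
(the original study used 1000 replicates). All randomness flows through
numpy Generators seeded from a single user seed; a fixed seed makes
simulation, construction, filtering and benchmark outputs byte-identical
across runs.

## What the synthetic benchmark does not show

The generator emulates seasonality-driven indirect associations, but not:
compositionality of sequencing data, sampling zeros and sparse counts (only
optional Poisson noise), time-delayed interactions, more than two
environmental factors, higher-order interactions, or non-stationary
environments. The stand-in constructor differs from eLSA in normalization
and p-values, so published network-size and removal-percentage medians are
reproduced qualitatively (orderings, precision levels), not numerically.
PPV on real data is unknowable without experimental truth; the benchmark's
PPV statements apply to the simulated regime only.
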