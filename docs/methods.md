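# Methods

## The sgFC transform

Functional connectivity (FC) between two cortical regions decays with
their Euclidean separation, and pairs joined by a direct structural
connection (SC) carry systematically stronger FC than pairs that are
not. `sgfc` uses both regularities as a frame of reference: the
monosynaptic (SC-connected) FC weights at a given distance define what
a functional connection of that length "should" look like, and every
polysynaptic (SC-unconnected) weight is re-expressed as a z-score
against that reference.

Concretely, all off-diagonal node pairs are assigned to equal-width
Euclidean-distance bins spanning the full range of pairwise distances
(half-open bins, the last closed, so every pair falls in exactly one
bin). Within each bin the mean μ_b and sample standard deviation σ_b
(n−1 denominator) of the *connected* FC weights are recorded; a bin is
valid only if it contains at least `min_connected_per_bin` connected
edges (default 2) with non-zero spread. Each unconnected pair in a
valid bin receives z = (FC − μ_b)/σ_b; connected pairs and the
diagonal are undefined (NaN) by construction. Pairs in invalid bins
are undefined under the default policy, or may borrow the nearest
valid bin's statistics under the `merge_nearest` policy — the default
refuses to fabricate reference statistics.

Two choices control resolution:

- **Bin count.** The Freedman–Diaconis rule, h = 2·IQR·n^(−1/3),
  applied to the *connected* edge lengths (they define the reference
  distribution whose resolution the bins must respect); the count is
  ceil(span/h), computed with a 1e-9 relative guard so exact integer
  ratios do not round up through floating-point error. A zero IQR
  falls back to Sturges' rule with a logged warning.
- **Smoothing.** Any single binning imposes arbitrary boundaries, so
  the final map averages the z-scores over every integer bin count in
  [round(0.75·B), round(1.25·B)] around the base count B (halfwidth
  configurable, rounding half away from zero). A pair's value is the
  mean over the spectrum members in which it is defined; pairs defined
  nowhere stay undefined. Provenance (base count and spectrum) is
  recorded on the output.

A distance-blind baseline — z-scoring polysynaptic FC by the *global*
connected mean and standard deviation, equivalent to a single bin — is
provided for comparison ("structure-only" correction).

Self-consistency is exact by construction: z-transforming the
connected edges by their own bin statistics returns mean 0 and sd 1
in every valid bin to machine precision, and the implementation is
tested against an independent per-pair brute-force transform to
< 1e-12 on small instances.

## Group-consensus structural connectome

Individual tractography reconstructions disagree, and a naive
frequency threshold over-selects short edges because short edges are
reconstructed more consistently. The consensus procedure therefore
pools every edge observed in any subject, bins pooled edges by length
(equal-width bins over each class's occupied range; the bin count is
round(sqrt(mean per-subject edge count)), at least 1), and keeps, per
bin, the k most frequently occurring edges, where k is the rounded
mean per-subject edge count in that bin. Frequency ties break by
higher mean weight, then lexicographic (i, j), making the output
deterministic. The procedure runs separately for intra- and
inter-hemispheric edges (the latter are long and would otherwise be
under-represented). A retained edge's weight is its mean over the
subjects that possess it — averaging over all subjects would
zero-inflate weights of less consistent edges.

Guarantees, verified on synthetic cohorts: the consensus edge count is
within one rounding unit per bin per class of the mean subject count,
the consensus edge set is a subset of the subject union with weights
bounded by the contributing subjects', and the edge-length
distribution is at least as close (two-sample KS) to the pooled
subject distribution as a frequency-only consensus at matched density.

## Diffusion map embedding

Regions are embedded on smooth macroscale gradients by treating each
region's FC row-profile as a data point. Pairwise Gaussian affinities
K_ij = exp(−d_ij²/2σ²) are computed over Euclidean distances between
row-profiles (the two self-entries, fixed at 1, are excluded from each
comparison; σ = 1 by default). The affinity graph is turned into an
ergodic Markov chain via the α-normalized graph Laplacian
(K' = D^(−α) K D^(−α) with α = 1, then row-normalization), and the
chain's leading non-trivial eigenvectors are the embedding
coordinates. Eigendecomposition uses the symmetric conjugate
D'^(1/2) P D'^(−1/2) for stability; eigenvectors are mapped back,
unit-normalized, and sign-fixed deterministically (largest-magnitude
entry positive), with `orient_gradient` flipping components to
correlate positively with a caller-supplied reference. A disconnected
affinity graph is rejected (the chain would not be ergodic). An
option to use the (shifted) FC matrix directly as the affinity is
exposed, since the toolbox semantics the field uses leave that choice
ambiguous; the row-profile reading is the default.

## Spin permutations and enrichment

Node-level maps are spatially smooth, so label-shuffling nulls
overstate significance. The spin null draws a uniform random 3-D
rotation per permutation, applies it to the left hemisphere's
spherical coordinates and its x-mirror conjugate to the right's, and
reassigns indices by greedy one-to-one nearest matching (ascending
match distance) within hemisphere. Greedy one-to-one matching — rather
than independent nearest-neighbor assignment — keeps every permutation
an exact bijection, so the value multiset is preserved and hemisphere
membership never changes; the identity rotation reproduces the
identity permutation exactly.

Network enrichment compares a map's values inside each network against
all other nodes with a pooled-variance two-sample t statistic; the
null distribution is the same statistic over the spun maps, the
p-value is two-sided with the +1 correction (never exactly zero,
floor 1/(n_perms+1)), Cohen's d is reported, and significance is
Bonferroni-corrected over the testable networks. The parametric t-test
p is emitted alongside for reference only. Degenerate cases (constant
maps, sub-2-member networks) return t = 0 / p = 1 or NaN rows rather
than errors. Under a label-independent white-noise map the permutation
p-values are uniform (KS-tested in the acceptance suite).

## The synthetic generator and its study conditions

The generator produces spatially embedded connectomes with enough of
the empirical phenomenology for every stage of the pipeline to be
exercised and scored against planted ground truth.

**Geometry.** n regions (default 200) split evenly between two
hemispherical shells of radius 50 mm whose centers are 100 mm apart,
each shell opening away from the midline; all inter-hemispheric
distances therefore exceed all intra-hemispheric ones, reproducing the
long-distance dominance of callosal pairs. The planted hierarchy
`gradient_truth` is the normalized distance from the midline plane, a
smooth bilaterally mirrored map whose apex sits at the lateral poles —
so apex-apex pairs span the longest distances, as transmodal hubs do.
Seven intrinsic-network analogues are consecutive gradient bands
(spatially contiguous, bilateral), named for the canonical networks in
hierarchy order (visual → default).

**Structural connectome.** Edges appear independently with probability
proportional to a mixture of exp(−d/30 mm) and (weight 0.5) a
distance-uniform component, normalized to 2% expected density. The
uniform component keeps a thin tail of long-range connections — as
deterministic tractography does — without which the distance-matched
reference distribution would be empty exactly where the interesting
polysynaptic edges live. Weights decay with distance with lognormal
scatter, mimicking streamline counts.

**Functional connectome.** Built directly in matrix space (not via
latent time series), trading positive-semidefiniteness for exact
control of planted effects (a Higham nearest-correlation projection is
available but off by default; the transform consumes weights, not
covariance structure). The upper triangle is assembled from:

1. a distance-decay baseline 0.25·exp(−d/60 mm) — the amplitude is
   deliberately below 1 because empirical short-range FC saturates
   well under unity, and a full-amplitude geometric term would both
   clip against the [−1, 1] bound and dominate every row-profile
   (making the hemispheres near-disconnected in affinity space);
2. a +50% boost of the baseline on structurally connected pairs;
3. a gradient-similarity kernel 0.5·exp(−|g_i − g_j|/0.35): regions at
   nearby hierarchy positions coactivate, in both hemispheres alike.
   This is the planted 1-D manifold the diffusion embedding recovers;
   because it is symmetric along the gradient it adds no net
   strength ramp for the exponential fit to absorb;
4. a polysynaptic within-network coactivation excess
   0.5·(mean(g_i, g_j))⁸ on structurally unconnected same-network
   pairs — a sharply top-heavy term concentrating the excess in the
   apex band, the synthetic analogue of the transmodal phenomenon (the
   empirical within-network elevation is itself strongly top-heavy).
   It is restricted to unconnected pairs so the monosynaptic reference
   stays clean: hierarchy position and distance are confounded in any
   bilateral geometry, and an excess shared by connected pairs would
   be absorbed into the distance-binned means;
5. Gaussian pair noise, sd 0.06, inflated 3× on connected pairs —
   monosynaptic weights are heterogeneous far beyond measurement
   noise in empirical weight-vs-distance clouds, and the inflation
   keeps the polysynaptic pair noise at ~1/3 of the local reference
   sd so planted effects are detectable at the stated boost;
6. 30 planted anomalous edges among structurally unconnected pairs
   longer than the 75th distance percentile with both endpoints in the
   planted node subset (top 1/7 of regions by gradient), each boosted
   by 3× the local sd of connected weights at comparable distance.
   The local sd is estimated in a widening ±12.5 mm window holding at
   least 10 connected edges, because a single sparse bin can report a
   near-zero sd and make the boost meaningless;
7. clipping to [−1, 1] and a unit diagonal.

**Cohorts.** Subject connectomes derive from a shared group truth by
deleting true edges with probability increasing linearly in length
rank (mean 10%, the longest edges dropped at twice the average rate —
long-streamline dropout) and inserting an equal expected number of
false edges whose lengths follow the group-truth length distribution.
This makes the frequency-only consensus measurably worse at length
preservation, which is precisely the regime the distance-binned
consensus was designed for; with uniform deletions both procedures
recover the truth and the comparison degenerates to ties.

**Seeding.** All randomness flows from one integer seed; each
stochastic stage derives an independent generator from (seed,
stage-tag) via `numpy.random.SeedSequence`, so stages are reproducible
in isolation and no global state is touched.

## What passing tests do and do not show

The synthetic conditions were designed so that each planted effect is
recoverable at desk scale (200 nodes, ~400 structural edges): planted
edges rank in the sgFC top 60 (median recovery 100% over 20 seeds),
the apex band tops the strength-residual enrichment and survives
Bonferroni at 1,000 spins in ≥ 90% of seeds, and the first diffusion
component correlates with the planted gradient at |r| ≳ 0.95. These
demonstrate that the implementation detects what it is supposed to
detect when the generating process matches its assumptions. They do
not certify behavior on real data, where FC is a noisy correlation
estimate with global-signal structure, SC reconstruction has
systematic (not independent) errors, and the hierarchy is not a known
scalar. Known small-sample caveats, visible at this scale:

- distance bins in the long tail can hold few connected edges;
  with the default `min_connected_per_bin = 2` an unlucky bin's sd
  may be estimated from 2–3 edges and its z-scores become volatile.
  Raising `min_connected_per_bin` or using `merge_nearest` trades
  coverage for stability; at the empirical scale (1,000 nodes, ~100
  edges per bin) the issue vanishes;
- the ratio of positive-part within-network means (sgFC/baseline)
  crowns the apex band only when the structure-only baseline is blind
  to its excess, as in empirical data; in synthetic regimes strong
  enough to drive edge recovery the baseline partially detects the
  excess and the ratio's denominator inflates. The package therefore
  reports the full ratio table but the synthetic tests assert the
  stable phenomenon (largest within-network sgFC mean);
- exponential strength-vs-strength fits are least-squares in log
  space over positive strengths (nodes with non-positive strength are
  excluded and counted), with R² reported in the original space; the
  fit's endpoint behavior is sensitive to smooth strength ramps.

## Problem sizes

Tests and the reproduction script use 200-node networks (the scale at
which all planted-recovery conditions are stated), 20-subject cohorts,
1,000 spin permutations for enrichment and 500 for the calibration
check, and 10–20 seed replicates per experiment; the full reproduction
script runs in about two minutes on one CPU.
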