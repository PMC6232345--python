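# Methods

## Signal model and scope

The pipeline treats each gray-matter voxel's BOLD series as a superposition
of frequency-localized processes on a 1/f-type background,
S(f) ∝ 1/f^γ with γ between 0.5 and 1.  All analysis operates on masked
voxel-by-time matrices with a known repetition time (TR); the reference
acquisition is TR = 0.645 s (fs ≈ 1.55 Hz, Nyquist ≈ 0.775 Hz) and 900
volumes per subject.  Preprocessing (realignment, normalization, smoothing,
motion regression) is outside the package's scope: inputs are assumed
aligned and masked, whether loaded from NIfTI or synthesized.

## Wavelet packet transform

The full WPT applies the Daubechies filter pair with 7 vanishing moments
(length 14) recursively to *both* branches of every node, producing 2^d
equal-width subbands at depth d and 127 nodes over depths 0–6.  Conventions:

- **Extension mode** is periodization, so the transform is orthogonal and
  per-depth energy equals input energy whenever node lengths stay even.
  Non-power-of-two lengths are handled by per-level ceil-halving (never
  truncation); once a node length becomes odd the periodized step
  duplicates one sample, making deeper levels slightly redundant — perfect
  reconstruction still holds to ~1e-14, but exact per-depth energy equality
  is only guaranteed for lengths divisible by 2^depth.  At 900 samples the
  depth-6 nodes hold 15 coefficients.
- **Frequency ordering.**  The high-pass branch mirrors the spectrum, so
  natural (paley) filter-bank order is band-shuffled.  Positions are
  exposed in frequency (sequency) order via the binary-reflected Gray code
  `natural = p ^ (p >> 1)`; this is what makes the nominal passband formula
  `[p, p+1]·(fs/2)/2^d` valid, and it is verified empirically by a
  sinusoid-sweep test.
- **Band edges are nominal.**  Finite filters leak: at depth 6 on
  900-sample signals, reconstructing the six-packet 12–194 mHz wideband set
  leaves 6–10% of energy outside the nominal edges.  Tests assert
  concentration, not perfection.
- **High-pass sign convention.**  The exposed filter pair uses the
  alternating-flip convention g[n] = (−1)^n h[L−1−n]; PyWavelets stores the
  same filter negated.  The global sign of detail coefficients affects no
  downstream quantity (energies, correlations, reconstructions).
- Voxel batches are transformed independently along the last axis; results
  do not depend on batch composition.

## Connectivity

For one packet, per-subject coefficient blocks are z-scored per voxel and
concatenated (subject order is irrelevant downstream).  Z-scoring is a
documented toggle, on by default: raw concatenation would let
between-subject amplitude differences dominate pooled correlations.
Functional connectivity is the Pearson correlation distance 1 − r over all
real packet coefficients (the periodized transform has no boundary region
to discard).  Zero-variance voxels have undefined correlations; they are
flagged with a warning and their distances set to NaN rather than silently
imputed.  Neighbor graphs keep, per voxel, the k = round(fraction·(n−1))
smallest-distance other voxels (fraction 0.05 by default); ties at the k-th
distance break toward the lower voxel index, and the voxel itself is always
excluded.  Distance matrices are dense, with a configurable voxel-count cap
(default 20 000); whole-brain scale would require chunked computation,
which is out of scope.

## Hierarchical clustering and inconsistency pruning

Average linkage (UPGMA) is computed by SciPy's `linkage`; an exhaustive
O(n³) re-implementation of the merge rule serves as an independent oracle
in the tests.  Merge ties on exactly equal linkage distances are resolved
by SciPy's deterministic nearest-neighbor-chain order (the oracle suite
uses tie-free random instances).

The inconsistency of link k is Y4(k) = (z(k) − Y1(k)) / Y2(k), where the
window of link k contains its own height and the heights of all links
within g − 1 dendrogram levels beneath it; Y1/Y2 are the window mean and
sample (n−1) standard deviation, and Y4 = 0 for degenerate windows (single
link, or zero spread).  `g = "global"` uses the link's entire subtree — the
operational meaning of a "global search" with g ≫ 2.  A strict
"at most g heights" window would make Y4 constant (1/√2) for every link
with one sub-link, since the z-score of a two-point sample is fixed; the
level-window convention used here is the standard one (identical to
MATLAB's and SciPy's `inconsistent`) and is cross-checked against SciPy in
the tests.

Pruning at threshold t removes every link with Y4 > t *and its dependents*:
a cluster is a maximal subtree containing no over-threshold link, so
cutting a link also invalidates the merges above it.  This matches
`fcluster(criterion='inconsistent')`.  Thresholds below the minimum yield
all singletons; at or above the maximum, one cluster; raising t never
increases the cluster count.  `prune_to_k` instead removes the k − 1
highest links and always yields exactly k clusters.  Leaf ordering for 1-D
dendrogram projections uses optimal leaf ordering (children of every merge
stay contiguous; adjacent-leaf dissimilarity is minimized) rather than an
unspecified greedy heuristic.

## Partition comparison

Entropy and mutual information use log base 2 throughout (outputs in bits)
with 0·log 0 := 0.  The variation of information
VI = [H(C′) − I] + [H(C″) − I] is unnormalized by default (a normalized
variant dividing by log2 n is available but off).  Cancellation residue
below 1e-12 bits snaps to exact zero, far below the smallest genuinely
nonzero VI at any realistic voxel count.

Meta-clustering of the packet-by-packet VI matrix reuses average linkage
plus inconsistency in two modes.  *coarse-local* cuts the single link with
the highest g = 2 inconsistency; *fine-global* cuts the lowest link whose
whole-subtree inconsistency exceeds a detect threshold among links joining
two subtrees that both contain designated packets (all packets by
default).  In both modes the cut removes the chosen link and its ancestors,
so the meta-clusters are the two subtrees under the cut plus each sibling
subtree along the path to the root; with a degenerate (all-zero) VI matrix
both modes return a single meta-cluster.  Which links count as "designated"
is a configuration input, mirroring analyses that anchor the cut inside a
band of interest.

## Voxelwise Jaccard maps

Neighbor sets are binary and unweighted; correlation magnitudes are
discarded after thresholding.  The wideband reference is the inverse WPT
keeping the six analysis packets D6P1, D5P1, D4P1, D5P4, D5P5, D4P3
(~12–194 mHz; fully configurable).  Graphs for this stage are built per
subject — not group-concatenated — because the map reports the mean and
standard deviation of each voxel's Jaccard distance across subjects.  The
Jaccard distance of two all-empty sets is undefined and raises rather than
returning a sentinel.

## Synthetic data

The generator emulates the study conditions the pipeline targets:

- **Background**: per-voxel 1/f^γ noise via spectral shaping (white-noise
  FFT × f^(−γ/2), DC zeroed, inverse FFT, unit variance).  Default
  γ = 0.75, the midpoint of the 0.5–1 range reported for BOLD.
- **Planted layers**: each layer is a ground-truth parcellation plus a
  passband and an amplitude.  Every cluster receives an independent
  band-limited series built by hard FFT-bin masking of white noise — exact
  band confinement by construction, so band-energy assertions are sharp.
  Voxel series are the amplitude-weighted sum of their clusters' signals
  plus background, z-scored per voxel (mirroring the implicit
  normalization of correlation analysis).
- **Default two-layer conditions** (used by the evaluation and acceptance
  script): 1000 voxels, 900 timepoints, TR 0.645 s, 3 subjects, two
  independent 6-cluster balanced parcellations at amplitude 2, active in
  24–48 mHz and 121–194 mHz.
- **Mask**: a Gaussian-smoothed random field thresholded at the quantile
  retaining the requested voxel count — irregular, blob-like, anatomy-free.
  Voxel order is C (row-major) flattening order of the mask volume,
  identical across all derived arrays.
- **Subjects** share ground-truth partitions but draw independent noise and
  signal realizations, matching a group-concatenation design.  All
  randomness derives from a single seed through `numpy.random.SeedSequence`
  spawning; identical configurations are bit-identical.

What the generator does *not* emulate: motion and physiological artifacts,
spatial autocorrelation of noise, hemodynamic response convolution,
between-subject anatomical variability, and any uncertainty about whether
mid-frequency structure in real data is signal or structured noise.
Passing recovery tests therefore demonstrates that the pipeline's machinery
is correct and sensitive under its own model, not that real BOLD data
contain such layers.

A consequence of finite filters worth knowing when interpreting
evaluations: packets spectrally adjacent to a planted band inherit its
parcellation through leakage, so subband partitions form contiguous
"families" around each planted band rather than isolated hits.  The
planted-recovery evaluation accounts for this by asserting co-clustering
of strictly-in-band packets and by using a far out-of-band packet
(D5P16, ~388–412 mHz) as the Jaccard contrast, rather than a packet inside
the six-packet wideband set, whose shared band-noise with the reference
confounds the comparison.

## Problem sizes and numerics

Default problem sizes (1000 voxels, 3 subjects, 10 replicates for the
stochastic evaluation; 50 replicates of 8192 samples for spectral-exponent
checks) are chosen so the full suite and the acceptance script each run in
about a minute on one CPU while leaving wide margins on every assertion
(e.g. in-band VI ≈ 0 vs ≈ 5.1 bits against the wrong layer; fitted slopes
within 0.01 of −γ).  Floating-point tolerances: filter conditions and
reconstructions at 1e-8 (observed ~1e-13); symmetry/linearity at 1e-10 to
1e-12; behavioral contrasts (leakage fractions, Jaccard orderings) at the
measured-margin level documented in the tests.
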