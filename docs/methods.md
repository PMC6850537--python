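# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `spikevat`, in the order a user meets them.

## Crisp partitions and validity indices

A hard k-partition of n objects is stored as a label vector with ids
compacted to 1..k in first-appearance order; the equivalent k×n binary
membership matrix (column sums 1, row sums > 0) is a derived view and the
conversion is lossless. Compaction makes relabeled inputs canonical, so
index computations are invariant to how a caller numbered their clusters.

**Dunn's index.** DI = min pairwise single-linkage set distance / max
cluster diameter. Both extremes are taken over explicit point pairs, so
DI is dominated by the closest cross pair and the widest cluster; DI > 1
characterizes a compact, separated partition, and values below ~0.5
indicate poor structure. **GDI₃₃** replaces the extremes with averages:
δ₃(Xᵢ,Xⱼ) = mean cross-pair distance, Δ₃(Xₖ) = 2 · mean distance to the
cluster centroid. Averaging discounts inliers/outliers, which is why
GDI₃₃ reads higher and smoother than DI on noisy spike data. Degenerate
denominators (all-singleton partitions) raise `ValueError` rather than
returning infinity, so a pipeline cannot silently score a meaningless
partition; k < 2 likewise raises.

**Adjusted Rand index.** Computed from the k×r contingency table as pair
counts a, b, c, e (same/same, V-only, U-only, different/different) and
the closed form 2(ae − bc)/[(a+b)(e+b)+(a+c)(e+c)]. When the denominator
is 0 (both partitions trivial — all one cluster or all singletons) the
convention is 1 for the identical partition and 0 otherwise; this corner
is not covered by the formula's usual derivation and is simply a
documented choice. The implementation is cross-checked in the tests
against an independent published implementation and an explicit
pair-enumeration oracle.

The only distance used by default is Euclidean distance on raw waveform
samples; every index accepts a pluggable metric callable (symmetric,
nonnegative) for other choices.

## VAT, iVAT and the single-linkage back pass

VAT starts Prim's MST construction at an endpoint of the globally largest
dissimilarity and records the vertex-insertion order; the reordered
matrix D\* is the input conjugated by that permutation. Two tie-breaks
make the ordering deterministic: among maximal entries the row-major
first one is used and its smaller index taken as the start; among
equidistant unvisited vertices the smallest original index is inserted
first. iVAT replaces d\*ᵢⱼ with the minimax path distance through the
MST via the O(n²) recursion over insertion order (for the r-th inserted
vertex with parent j: d′ᵣⱼ = d\*ᵣⱼ, d′ᵣc = max(d\*ᵣⱼ, d′ⱼc)); the tests
verify it against a full-graph Floyd–Warshall-style minimax oracle, which
also confirms that the MST suffices. Any symmetric nonnegative
zero-diagonal matrix is accepted — metric structure is not required.

Cutting the k−1 largest MST edges (ties: later-inserted edges first)
yields exactly the k-cluster single-linkage flat partition; the tests
check agreement with agglomerative single linkage for every k on random
instances. `estimate_cluster_count` — 1 + the number of edges above the
largest gap in the sorted MST edge weights — is a convenience heuristic
the block imagery motivates; it is never consumed by other operations and
can underestimate when clusters separate at different scales (the README
example shows exactly this).

Images are written as 8-bit grayscale PNG with linear intensity scaling,
round(255·d/max D): the simplest monotone map. No histogram equalization
is applied, so faint sub-blocks may need a higher-resolution look.

## 2-D representations

* **PCA**: projection onto the two leading eigenvectors of the sample
  covariance; each axis's sign is fixed so its largest-magnitude loading
  is positive (determinism for regression tests).
* **PV-E**: peak-to-valley is implemented as the *time* between the
  waveform maximum and minimum (seconds; flat waveforms give 0 via the
  first-index argmax/argmin convention), with an amplitude variant
  (max − min) behind the `pv_amplitude` flag; energy is the raw sum of
  squared samples with no sample-interval scaling.
* **Wavelet**: zero-pad to the next power of two, 4-level Haar transform,
  then keep the two coefficients whose distributions across the set are
  farthest (Kolmogorov–Smirnov distance) from a moment-fitted normal —
  the selection rule of the Waveclus lineage. Family, level and the
  selection count are configurable; at least 10 waveforms are required
  because the selection statistic is unstable below that.
* **t-SNE**: delegated to scikit-learn's Barnes–Hut implementation with
  PCA initialization. Defaults are perplexity 30, learning rate 500,
  2000 iterations — the standard operating point for spike sets with
  thousands of waveforms; template-level sets of ~10 means need
  perplexity 2–3, exposed as a parameter. Requires n > 3·perplexity.
* **Sammon**: minimizes E = (Σ Dᵢⱼ)⁻¹ Σ (Dᵢⱼ − dᵢⱼ)²/Dᵢⱼ by Sammon's
  diagonal-Newton descent from the PCA start, step 0.3 with step-halving
  whenever a step would increase the stress, 500 iterations default; the
  reported stress sequence is therefore monotone non-increasing, and
  three consecutive failed step-halvings raise a divergence error.
  Duplicate rows are jittered by 1e-9 of the data scale because zero
  upspace distances are inadmissible in the stress.

All five preserve row order and count; PCA/PV-E/wavelet are
deterministic, t-SNE and Sammon deterministic for a fixed seed.

## Simulator

The generator emulates the standard simulated-extracellular-trace
protocol. Templates are differences of two Gaussian lobes (randomized
valley/peak positions, widths and polarity in a 2 ms window, normalized
to unit peak amplitude); a distinctness constraint (pairwise zero-lag
correlation < 0.999 by default) replaces the diversity of a recorded
template library. Per-unit amplitudes follow Normal(1.1, 0.3) hard-
truncated to [0.9, 2] by rejection — the mean and range are the
protocol's; the SD is unspecified there and 0.3 is this package's
default, chosen to fill the permitted range without excessive rejection.
Background noise superimposes ≥ 1000 template instances at uniform random
offsets and rescales the trace so its population SD is exactly the target
(0.1 by default); being built from smooth spike shapes it is temporally
correlated, unlike white noise. Multi-unit activity draws one of 20
designated shapes with amplitude uniform on [0.3, 0.5] — the 0.5 cap is
the protocol's, the uniform law and lower edge are this package's choice.

Two assembly modes: waveform-level (noise segment added per window —
fast, used throughout the evaluation pipeline) and trace-level (continuous
trace, absolute-voltage threshold at 5 noise SDs, windows centered on the
local absolute extremum, labels by matching planted event times, with
missed events and false positives reported). Window alignment on the
extremum is a choice; the protocol does not state one.

What the simulator does **not** model: electrode drift, bursting
amplitude decrement, overlapping spikes within one window, and the full
waveform diversity of recorded template libraries. Tests passing on these
mixtures therefore demonstrate algorithmic correctness and the expected
qualitative behaviour (separable data are separable downspace; DI falls
as components are added), not performance on any particular recording.

## Evaluation pipeline

k-means (scikit-learn, random initialization) is run with k equal to the
number of ground-truth subsets, five replicates per space, keeping the
replicate with the lowest within-cluster sum of point-to-centroid
*distances*. That selection rule is read literally (unsquared sums) even
though k-means itself minimizes squared error; `squared_selection=True`
switches to squared sums, and on well-separated data the two agree.
Empty clusters cannot survive scikit-learn's update step, so no
re-initialization logic is needed beyond the replicate loop. One master
seed expands deterministically (via `SeedSequence`) into per-replicate
and per-embedding seeds, making whole evaluation records reproducible.

`validity_over_combinations` mirrors the subset-combination design for
labeled mixtures: from a fixed pool of per-unit waveform subsets, every
k-element combination is one mixture, and both Dunn-type indices factor
into per-subset and pairwise tables computed once. When all combinations
are used, mean DI is non-increasing in k by construction (every larger
combination contains smaller ones), which is the clean version of the
downward trend seen when averaging over mixtures; `max_combinations`
subsamples when the pool is large.

Problem sizes used in the test suite and acceptance checks — a 3-unit
mixture of 1500 waveforms for the end-to-end recovery check, a pool of 12
subsets × 40 spikes for the DI-by-k sweep, 10⁶ samples for the noise-SD
check — are the package's own choices: large enough for the statistics
asserted, small enough to run comfortably on one CPU.

## Known limitations

* `estimate_cluster_count` is a single-gap heuristic; hierarchical or
  multi-scale structure defeats it by design.
* The wavelet feature selection rule is one member of a family; other
  normality scores (e.g. Lilliefors) would select different coefficients.
* Embeddings are not standardized before k-means by default (the raw
  coordinate scales are used); pass standardized coordinates if the
  application calls for it.
* iVAT is O(n²) in time and memory; beyond a few tens of thousands of
  waveforms a sampling-based variant would be needed (not implemented).
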