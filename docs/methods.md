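# Methods

## Doublet-value mapping

A DNA sequence `s` of length `M` over {A, C, G, T} defines `M − 1`
overlapping ordered dinucleotides (doublets). Each doublet carries a real
value from a 16-entry table; the default assignment is

| | | | |
|---|---|---|---|
| AA = 0 | AT = 1 | TA = 2 | AG = 3 |
| TT = 4 | TG = 5 | AC = 6 | TC = 7 |
| GA = 8 | CA = 9 | GT = 10 | GG = 11 |
| CT = 12 | GC = 13 | CG = 14 | CC = 15 |

The signal sample at position `n` combines the `α` doublet values starting
at residue `n`. Three combiners are provided:

* **sum** (default): `x[n] = Σ_{j<α} v_j`. Summation both smooths the
  signal as α grows and enlarges the amplitude alphabet (values in
  `[0, 15α]`).
* **mean**: sum divided by α (same shape, normalised level).
* **positional**: `Σ_j 16^j v_j`, a radix encoding that makes every
  window content distinguishable (K-strings style).

The exact combining rule is a genuinely open design point; sum is the
default because it delivers both observable behaviours (smoothing and a
larger alphabet) with the least structure. The signal length convention
is `M − α` (every window fully inside the doublet stream).

Consequences used as test invariants: a single substitution at residue
`p` perturbs only samples `n` with `n ≤ p ≤ n + α` (≤ α + 1 samples,
a *vertical* shift); an indel leaves the head of the signal intact and
shifts the tail *horizontally*; with α = 1 the default table is injective,
so the doublet stream — and the sequence, given its first base — is
recoverable from the signal.

**Defaults.** α = 3: small enough to keep single-substitution resolution,
large enough to smooth; exposed everywhere as a flag. Non-ACGT residues
are a hard error by default (ambiguity codes have no doublet value); a
`drop` policy removes them before mapping.

## Wavelet denoising

The observed signal is modelled as clean part plus additive noise;
because the orthogonal DWT is linear, the noise spreads across many small
detail coefficients while the informative component concentrates in a few
large ones. Denoising = DWT → per-level soft thresholding of detail
coefficients → inverse DWT. Approximation (low-frequency) coefficients are
never touched.

Per level, the threshold is chosen by SureShrink: the minimiser of
Stein's unbiased risk estimate of the soft-threshold estimator over the
candidate set `{|c_i|/σ}`, capped at the universal threshold
`√(2 ln n)`. The noise scale σ is the median absolute deviation of the
finest detail level divided by 0.6745. In the sparse regime (the
standard `s² ≤ n^(−1/2)(log₂ n)^(3/2)` test) SURE is unreliable and the
hybrid rule substitutes the universal threshold; `threshold_rule="sure"`
disables the fallback.

**Defaults and numerical choices.** Wavelet db4 (8-tap orthogonal
Daubechies), level `min(4, max depth)`, symmetric boundary extension
(fewest edge artifacts on non-periodic genomic signals). A constant
signal has zero detail energy, σ = 0, and passes through unchanged.
Tested properties: perfect reconstruction when no coefficient is touched
(1e−8), energy non-increase under soft thresholding, noise reduction on a
seeded noisy sinusoid, near-idempotence.

## Spectrum distance

All signals in a comparison set are right-zero-padded to the maximum
signal length `N`, DFT'd, and squared (`P(k) = |X(k)|²`, full two-sided
spectrum). The pairwise distance is the MSE `(1/N) Σ_k (P₁ − P₂)²`. No
DC removal and no amplitude normalisation are applied by default (both
available as flags, since sequence length and composition shift DC
energy). The distance is symmetric, nonnegative, and exactly zero for
identical signals; the triangle inequality is **not** claimed and should
not be assumed. Comparing over all `N` bins rather than up to Nyquist
doubles each squared difference's weight symmetrically and does not
change any ordering.

## Trees and the cluster overlapping score

Neighbor joining is implemented directly (Saitou–Nei agglomeration with
the Studier–Keppler selection criterion) because the contract here is
stricter than what library implementations guarantee: ties are broken
deterministically toward the lowest-index pair, and negative branch
length estimates are clamped to zero. On additive matrices the
implementation recovers the generating topology and all path distances
(cross-checked against an independent NJ implementation in the tests).

A *cluster* is the leaf set behind an internal edge — never the full
leaf set and never a single leaf, so an `n`-leaf binary tree has `n − 3`
clusters, each stored canonically by its smaller side. The overlap score
between two trees on identical leaves matches every cluster of each tree
to its best-overlapping cluster of the other under the Dice coefficient
(evaluated complement-aware, because unrooted splits have no orientation)
and averages all per-cluster maxima. This symmetric best-match mean was
chosen over a pair-averaged variant because it is symmetric and anchors
self-comparison at exactly 1; an asymmetric one-directional variant is
available behind the `symmetric=False` flag. A star tree has no
qualifying clusters; its score against anything is defined as 0 with a
warning. Scores are kept in [0, 1] internally and ×100 in emitted
tables; table aggregation defaults to the sample (n − 1) standard
deviation with the population convention available via `ddof=0`.

## Similarity descriptors

For equal-length signals `x`, `y`:

* `ρ = |corr(x, y)|` — absolute Pearson correlation; the sign is
  discarded because only the degree of linear association matters.
* `C` — mean magnitude-squared coherence `|S_xy|²/(S_xx S_yy)` over 128
  equally spaced frequencies in (0, 0.5] cycles/sample, with the spectral
  matrix `S(f) = H(f) Σ H(f)*`, `H(f) = (I − Σ_k A_k e^(−i2πfk))^(−1)`,
  estimated from a bivariate AR(p) model fitted by conditional least
  squares on mean-centred channels. Default p = 10, capped at a tenth of
  the series length (and ≥ 1 for very short signals). An exactly
  identical pair short-circuits to 1; a singular innovation covariance is
  regularised by a diagonal load of 1e−8 × trace.
* `D̄` — mean |Δx − Δy| of the first forward differences; 0 means
  identical trend. Differencing removes the constant level shift a
  substitution imprints, so `D̄` responds to shape changes (indels) more
  than to substitutions. "Mean slope difference" admits another reading
  (difference of the two mean slopes), which collapses nearly all
  information into one number and is not implemented as default.

Pairs of unequal length (indels) are compared on the common-length
prefix — the least-surprising choice given that the dictionary assay
always compares same-length windows.

Descriptors are computed on **raw** (un-denoised) doublet signals: they
are local shape measures and thresholding would blur exactly the
perturbations they resolve. Denoising remains in the distance pipeline.

## Dictionary domain search

A reference signal is tiled left-to-right into non-overlapping fragments
of length W (default 100 samples; the trailing remainder is dropped).
Each fragment slides over each target with step 1; an offset is a hit
when `ρ > 0.9`, `C > 0.9` and `D̄ < 0.8` simultaneously at that single
offset. Correlation and derivative are screened first in vectorised
form; the AR coherence is evaluated only at surviving offsets — the hit
set is identical because acceptance is a conjunction. Signal coordinate
`n` maps back to residue interval `[n, n + α + 1)`.

## Synthetic data

The generators emulate controlled-mutation experiments, with every draw a
pure function of (parameters, seed):

* `random_sequence(n, seed)` — i.i.d. uniform bases.
* `cumulative_substitution_series(template, (1, 3, 5, 10), seed)` —
  nested substitution sets at distinct positions, so the k-th mutant is
  at exactly the stated Hamming distance.
* `progressive_mutation_set(template, 10, 0.20, seed)` — rounds of 10
  substitutions in previously untouched bases until 20 % of the template
  has changed (200 sequences for 10 kb).
* `exhaustive_neighborhood(template, 3, kinds)` — every distinct variant
  within k ≤ 3 changes of one kind (for 20 nt substitutions: 60 / 1,710 /
  30,780 variants), deduplicated; change types are enumerated separately,
  not mixed. A guard refuses enumerations beyond 10⁶ variants.

What the generators do **not** emulate: realistic base composition,
transition/transversion bias, indel length distributions, rate
heterogeneity, or any evolutionary model. Passing tests therefore show
that the machinery behaves as designed under uniform random conditions,
not that the distance is a consistent estimator of evolutionary
divergence on real genomes.

## Problem sizes in the test battery

The study-level checks run at these scales: distance monotonicity on
10,000 nt templates over 20 seeds (means of 1/3/5/10 cumulative
substitutions); descriptor-space ordering on 20 nt templates with the
exhaustive substitution neighborhood to k = 3 over 10 seeds, and the
indel-versus-substitution centroid separation with exhaustive
neighborhoods to k = 2 per kind (exhaustive triple insertions alone
exceed 110,000 variants per seed and add nothing to a sign test);
NJ consistency on 100 random additive matrices with up to 12 leaves;
dictionary search on 1,000 nt templates over 100 seeds.

## Known limitations

* The spectrum MSE is dominated by DC and low-frequency energy; sequences
  of very different lengths or compositions compare mostly by those bins
  unless `remove_dc`/`one_sided` are enabled.
* The distance is not a metric (no triangle inequality), so methods that
  require metricity should not consume it blindly.
* AR-based coherence is sensitive to the model order; on short windows
  the order cap (length/10) can force p = 1, which flattens the spectral
  estimate.
* The cluster overlapping score saturates quickly for large trees that
  share many shallow splits; it is a similarity score, not a proper
  tree-distance.
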