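# Methods

This note documents the models and procedures implemented in `microsketch`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open. No empirical claim is made here beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## K-mer encoding

Reads are decomposed into overlapping windows of length `k` (default 21,
1 ≤ k ≤ 31). Each window whose bases are all in {A, C, G, T} is packed two
bits per base (A=0, C=1, G=2, T=3, first base most significant) and the
*canonical* value is the numeric minimum of the forward and
reverse-complement packings, so a read and its reverse complement produce the
same multiset of k-mers. Windows containing any other symbol are skipped
rather than substituted: substitution would fabricate k-mers that were never
sequenced. Optional 3' quality trimming uses the BWA-style running-sum rule
(cut maximizing `Σ(q_min − q_i)` from the read end); it defaults to off so
sketches are reproducible without it.

## Counting: count-min sketches

All counting happens in count-min sketches: `depth` tables of `width`
real-valued counters, with per-table seeded splitmix64 hashing. Dimensions
derive from a relative accuracy `ε` and confidence `δ` as
`depth = ⌈log(1−δ)/log ½⌉`, `width = ⌈2/ε⌉`; the defaults ε = 10⁻⁴, δ = 0.9
give 4 × 20 000 counters. These formulas were chosen because they reproduce
that dimension pair exactly; the alternative classical parameterization
(`⌈e/ε⌉`, `⌈ln(1/δ)⌉`) does not. Estimates are minima over tables and
therefore never underestimate; counters are floats so decay scaling composes
exactly with counting. δ is interpreted as the confidence with which the
ε·N overestimation bound holds (N = total added mass).

## The histogram and its sketch

K-mers are assigned to `X` histogram bins by a seeded 64-bit mix hash modulo
`X`. `X` defaults to 80 000 — the count-min counter budget (4 × 20 000) —
keeping bin identity well defined while honouring the fixed-counter budget;
any `X ≥ 1` may be configured, and all comparisons require equal
`(k, Z, X, master_seed)`.

Consistent weighted sampling hashes bin `i` for slot `j` as

    y_ij = exp(log W_i − r_ij β_ij),   a_ij = c_ij / (y_ij e^{r_ij}),

with `r, c ~ Gamma(shape 2, scale 1)` and `β ~ Uniform(0,1)`. The Gamma
parameterization follows the consistent-weighted-sampling literature (the
density `x e^{−x}`), which is what makes the scheme's selection exactly
proportional: algebraically `a_ij = V_ij / W_i` where
`V_ij = c_ij e^{−r_ij(1−β_ij)}` is an Exp(1) variate independent of the
weights (the product of a Gamma(2,1) and an independent Uniform(0,1) is
Exp(1), applied twice). Hence

* P(bin i wins slot j) = `W_i / Σ W` exactly (verified by chi-square in the
  acceptance tests), and
* for two spectra sketched under the same seed the slot-collision
  probability is the *probability Jaccard*
  `J_P(u, v) = Σ_i 1 / Σ_j max(u_j/u_i, v_j/v_i)`,

an approximation of the weighted Jaccard `J_W = Σ min / Σ max` that is exact
whenever the two spectra place equal weight on their shared support (e.g.
communities differing by taxon replacement at equal abundances) and close
when shared-bin weights are similar. The similarity-preservation test
measures the achieved bias directly against a brute-force `J_W` oracle and
requires it to stay within 3·√(J(1−J)/Z).

All CWS variates are *lazy and counter-based*: pure splitmix64 functions of
`(bin, slot, master_seed)`, never precomputed — storing 3·X·Z reals would
defeat the fixed-memory goal. Exp(1) variates are built as `−log u` from
top-53-bit uniforms offset half an ulp away from {0, 1}.

### Creation, update, decay

Creation takes, per slot, the argmin of `a_ij` over nonzero bins (ties to
the lower bin index). Incremental update re-hashes an incoming bin at its
*cumulative* count-min estimate and replaces any slot where the new hash is a
strict improvement (equal hashes keep the incumbent). Because `a` is
monotone decreasing in the weight and depends only on the cumulative count,
the final sketch is bit-identical to one-shot creation for every ordering and
partition of the input — the property the streaming architecture relies on,
and the reason flushes can use deterministic ascending-bin order rather than
a randomized one.

Streaming (`sketch_stream`) deals reads round-robin to `num_counters` local
count-min stores; every `interval` reads a counter flushes its touched bins
into the persistent sketcher count-min, updates the sketch, wipes its local
store, and a snapshot is yielded (plus always a final one). Concept drift is
handled by a decay weight `w = 1 − decay_ratio` applied once per flush:
counters are scaled by `w` and the stored minima `A_j` divided by `w`, so old
winners become progressively easier to displace. The per-flush schedule is a
design choice (per-read and per-sample-boundary variants would differ only in
the effective half-life); `decay_ratio = 0.02` is used in the streaming
classification tests, 0 (off) elsewhere and by default.

Multiple counting processes change throughput, never results (exactly true
with decay off; with decay on, flush *timing* matters and the deterministic
round-robin schedule keeps runs reproducible).

## Distances

Jaccard similarity is the slot match rate. For the weighted metrics each
slot contributes a weight surrogate `u_j = 1/A_j`, monotone in the winning
bin's weight; the weighted Jaccard distance takes the intersection term
`min(u_j, v_j)` only over slots whose bin identifiers agree (disagreeing
slots share no mass) and the union term over all slots. The surrogate
transform is switchable (`inverse`, `raw`, `rank`) behind one function since
the best choice is an open design question; `inverse` is the default.
Bray-Curtis and Euclidean are the standard formulas over the surrogate
vectors (scipy implementations).

## LSH forest

An index at similarity threshold `t` splits each sketch's first `K·L` slot
values into `L` chunks of `K` uint32 values, serialized little-endian as the
table keys. Tuning scans all integer pairs with `K·L ≤ Z` under the banding
model `p(s) = 1 − (1−s^K)^L`, scoring `FN = 1 − p(t)` and `FP = p(t − m)`
with a fixed margin `m = 0.05` (configurable; the margin is a package choice,
not an external constant), and picks the minimal `FP + FN` with ties toward
larger `K`. Query candidates (≥ 1 chunk collision) are post-filtered by
exact slot Jaccard, so returned neighbours always satisfy the threshold —
only recall is probabilistic, at the tuned FN rate. An unfiltered mode
returns raw candidates. The index serializes to versioned JSON; tables are
rebuilt from the stored entries at load, which keeps the on-disk format
implementation-independent.

## Classification

Features are the raw `S`-vectors only — bin identifiers, not hash values.
Training performs a stratified 80/20 split (stratification and the fixed seed
are reproducibility choices), fits a 1000-tree bootstrapped random forest,
reports held-out accuracy/F1/precision/recall and a stratified 10-fold
cross-validation summary over the full data (folds reduced to the minority
class count when below 10). An optional `frequency` encoding (bin-count
vectors) is available because tree splits on arbitrary integer identifiers
are representation-sensitive; the default stays with the raw identifiers.
Streaming prediction classifies snapshots as they arrive and returns the
first result whose maximum class probability reaches the threshold
(cooperative termination: the caller stops the sketcher), or the final
snapshot flagged below-threshold.

## Synthetic data

Communities are `n` i.i.d.-uniform ACGT genomes with uniform, lognormal
(σ = 1) or explicit relative abundances. At k = 21 random genomes share
k-mers with negligible probability, so overlap between communities is
controlled purely by shared taxa and abundances, and the exact spectrum
(dictionary count of canonical k-mers, abundance-weighted for a community,
unit-weighted for reads) is a closed-form oracle for weighted Jaccard.
Perturbations: `taxon-swap` replaces `⌈shift·n⌉` genomes; `abundance-shift`
moves `shift` of the mass toward a random Dirichlet profile. Reads have
uniform start/strand, substitution-only errors and flat qualities —
deliberately minimal: enough to stress canonical encoding, window skipping
and trimming, but not a model of platform noise (no indels, no quality decay,
no host contamination). Passing tests therefore demonstrate the sketching
mathematics and pipeline correctness, not robustness to realistic error
profiles.

### Problem sizes used in the tests

The test suite runs at desk scale, chosen so the whole suite completes in a
few minutes while keeping every statistical check well powered: spectra of
X = 1000–32 768 bins, sketches of Z = 128–512 slots, communities of 10–20
genomes of 250–500 bp, 200–800 reads per sample, 12–30 samples per
experiment, 12–20 seed replicates. The clustering experiment uses 5
communities × 6 replicate read samples at Z = 512; the classification
experiment uses two classes at taxon-swap 0.5, 60 samples, the default
1000-tree forest, and streams of 800 reads at sampling intervals of 50/200/
800 reads with decay 0.02 and probability threshold 0.9 (flush counts
compared as means over 12 stream seeds, since single-stream forest
probabilities are not monotone in reads). k = 21 is used throughout the
synthetic experiments because random genomes are k-mer-disjoint there, which
makes planted structure analytic; at k = 7 every canonical 7-mer occurs in
any random genome and class separation would rest on frequency noise alone.

## Numerical choices and degenerate inputs

* Empty slots: `S_j = −1`, `A_j = +∞` until the first update (any finite
  hash wins); sketches with unfilled slots refuse comparison/indexing.
* All-zero spectra and streams with zero valid k-mers raise errors rather
  than returning degenerate sketches.
* Ties on hash values keep the incumbent (updates) or the lower bin index
  (creation); with continuous hashes ties have measure zero.
* uint64 hashing wraps modulo 2⁶⁴ by construction; uniforms avoid exact
  0 and 1 so logs are finite.
* Sketch files are little-endian binary with a versioned `HSKT` header; a
  JSON export mirrors the same fields.

## Known limitations

* The weighted-Jaccard surrogate (`1/A` on agreeing slots) and the
  slot-collision ≈ `J_P` ≈ `J_W` approximation are exact only for
  equal-weight shared support; strongly skewed shared abundances widen the
  gap between estimated and true weighted Jaccard.
* Local counting stores are themselves count-min sketches, so with very
  narrow widths local collisions can inflate flushed counts and break exact
  order-independence; the equivalence tests run at widths where the
  collision probability is negligible, mirroring the default 20 000-slot
  tables.
* Decay makes results depend on flush timing by design; reproducibility is
  guaranteed only for a fixed (interval, num_counters) schedule.
* FASTA input, paired-end awareness, adapter trimming and realistic error
  models are out of scope.
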