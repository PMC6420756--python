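# microsketch

Fixed-memory, streaming comparison and classification of microbiome
sequencing samples via **histosketches** of the k-mer spectrum.

## The problem

Comparing shotgun metagenome samples by their k-mer spectra (the histogram of
canonical k-mer frequencies) is a standard alignment- and reference-free way
to measure community dissimilarity — but full spectra are enormous, and plain
MinHash sketches discard the frequency information that distinguishes
abundance shifts from presence/absence changes. `microsketch` maintains a
small, fixed-size, *similarity-preserving* summary of the weighted spectrum
that can be updated incrementally while reads are still streaming off the
sequencer, so samples can be compared, looked up in an index, or classified
before sequencing even finishes.

## The method

Reads from a FASTQ stream are decomposed into canonical k-mers (2-bit packed
uint64, the minimum of the forward and reverse-complement encodings) and
hashed uniformly into `X` histogram bins. Bin frequencies are tracked in
count-min sketches — `d × w` counter matrices with
`d = ⌈log(1−δ)/log ½⌉, w = ⌈2/ε⌉` (4 × 20 000 at the defaults
ε = 10⁻⁴, δ = 0.9) — so counting memory is fixed regardless of sample size.

The spectrum `V` (bins `i = 1…X` with weights `W_i`) is reduced to a Z-slot
**histosketch** by consistent weighted sampling. For slot `j`, every nonzero
bin receives the hash

```
y_ij = exp(log W_i − r_ij β_ij)        a_ij = c_ij / (y_ij exp(r_ij))
```

with `r_ij, c_ij ~ Gamma(2, 1)` and `β_ij ~ Uniform(0, 1)` drawn as pure
functions of `(i, j, master_seed)`. Slot `j` keeps the winning bin
`S_j = argmin_i a_ij` and its hash `A_j = min_i a_ij`. Because
`a_ij` is an Exp(1) variate divided by `W_i`, bins win slots in proportion to
their weight, and the fraction of slots two sketches share estimates the
similarity of the underlying spectra. Keeping `A` makes the sketch
incrementally updatable: new counts re-hash a bin at its cumulative
count-min estimate and take over any slot where they achieve a new minimum —
so the final sketch is **identical** whether the spectrum arrived in one
batch or as any ordering/partition of increments. An optional decay weight
(`1 − decay_ratio` per flush) gradually forgets old mass so streaming
sketches track concept drift.

On top of the sketches the package provides:

* **distances** — Jaccard (slot match rate), weighted Jaccard
  `1 − Σ min(u,v)/Σ max(u,v)` over per-slot weight surrogates `u = 1/A`,
  Bray-Curtis and Euclidean, plus all-vs-all CSV matrices;
* **LSH-forest indexing** — sketches split into `L` chunks of `K` slot
  values with `(K, L)` self-tuned against the banding collision model
  `p(s) = 1 − (1 − s^K)^L` at a chosen similarity threshold; candidates are
  post-filtered so reported neighbours always meet the threshold;
* **classification** — a bootstrapped 1000-tree random forest on the raw
  `S`-vectors (80/20 stratified split, 10-fold CV report), including
  streaming prediction that stops a read stream as soon as a class
  probability threshold is reached;
* **synthetic communities** — random-genome communities with known
  abundances, exact spectrum oracles and plantable overlaps, used throughout
  the test suite.

## Worked example

Simulate two replicate read samples from one community and a third sample
after half its taxa were replaced, sketch all three, and compare:

```sh
microsketch simulate --n-taxa 12 --genome-length 500 --n-reads 500 \
    --seed 1 --read-seed 11 > baseline_rep1.fastq
microsketch simulate --n-taxa 12 --genome-length 500 --n-reads 500 \
    --seed 1 --read-seed 12 > baseline_rep2.fastq
microsketch simulate --n-taxa 12 --genome-length 500 --n-reads 500 \
    --seed 1 --shift 0.5 --read-seed 13 > shifted.fastq

for f in baseline_rep1 baseline_rep2 shifted; do
    microsketch sketch -f $f.fastq -o $f.sketch -z 512 -x 8192
done

microsketch distance baseline_rep1.sketch baseline_rep2.sketch -m jaccard
microsketch distance baseline_rep1.sketch shifted.sketch -m jaccard
microsketch smash -d . --wjsMatrix
```

prints

```
baseline_rep1.sketch baseline_rep2.sketch jaccard 0.804688
baseline_rep1.sketch shifted.sketch jaccard 0.486328
,baseline_rep1,baseline_rep2,shifted
baseline_rep1,1.0,0.7614191381235517,0.38853991095158824
baseline_rep2,0.7614191381235517,1.0,0.3661477040859289
shifted,0.38853991095158824,0.3661477040859289,1.0
```

The two read-resampled replicates of the same community share ~80% of their
sketch slots, while the half-swapped community drops to ~49% — close to the
≈0.5 weighted-Jaccard overlap planted by replacing half the taxa. The
`smash` matrix reports the corresponding weighted Jaccard similarities.
Sketches pipe: `microsketch simulate … | microsketch sketch --stream -i 100 |
microsketch predict -m model` classifies a stream snapshot-by-snapshot and
stops at the probability threshold.

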