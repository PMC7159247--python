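# Methods

## Feature representation

A sequence is represented by the concatenated canonical k-mer frequency
vectors for k = 3..7 (dimension 10952). Conventions, all frozen into the
feature-layout signature that is serialized with every model:

- **Canonical form** is the lexicographic minimum of a k-mer and its
  reverse complement under A < C < G < T — the standard convention, which
  makes the representation strand-invariant.
- **Ordering**: blocks by ascending k, canonical k-mers lexicographic
  within a block.
- **Normalization is per k-block**, not global: each block sums to 1
  whenever the sequence has at least one valid window of that width.
  This keeps every k's contribution on the same scale regardless of
  sequence length and prevents the 8192-dimensional 7-mer block from
  numerically swamping the 32-dimensional 3-mer block.
- **Ambiguous characters**: any window containing a non-ACGT character is
  skipped deterministically (no random base resolution). A sequence
  shorter than k, or with no valid window of width k, gets an all-zero
  k-block.

Counting is vectorized (2-bit packed codes, a precomputed code→canonical
column map per k, `bincount`); a naive window-by-window counter with
exact rational normalization serves as the oracle in the tests.

## Classifier

One L2-regularized logistic regression per training length
{1 kb, 10 kb, 100 kb, 500 kb}, fitted with lbfgs (tolerance 1e-4, a
deterministic solver given fixed data order). The regularization
parameter is the conventional inverse strength C, default 1.0, exposed in
`TrainingConfig`. A query of length L is dispatched to the nearest
training length; the induced ranges are left-open/right-closed, so
L = 5500 goes to the 1 kb model and L = 5501 to the 10 kb model. A
probability of exactly 0.5 is labeled chromosome (the plasmid rule is
strictly "> 0.5").

Training fragment counts: the 1 kb and 10 kb bins use a fixed per-class
count (`n_short`, default 90 000, scaled down in tests and benchmarks);
the 100 kb and 500 kb bins derive the plasmid count from covering all
sufficiently long plasmids to depth `depth_long` (default 5), i.e.
`ceil(depth × Σ eligible_len / L)`, and sample the chromosome class to
the same count so every bin trains balanced. Reference databases rarely
contain plasmids above 100 kb, so on small reference sets the long bins
may be untrainable; such bins are omitted with a warning and dispatch
falls back to the nearest available smaller bin (graceful degradation
rather than failure).

Fragment sampling draws a reference with probability proportional to
`len − L + 1` over references of length ≥ L, then a uniform start — this
makes the draw uniform over *all* possible fragments, the most natural
reading of sampling "from the reference sequences with replacement";
per-reference-uniform choice is available as a config alternative.
Held-out splits are always by reference, never by fragment, so no
evaluation fragment shares a source sequence with training. Tiled
evaluation fragments use stride L/2 with a final end-anchored fragment,
guaranteeing ≥ 1× coverage of every base.

## Evaluation

Metrics count sequences (plasmid = positive): precision = tp/(tp+fp),
recall = tp/(tp+fn), F1 their harmonic mean, with zero denominators
mapped to 0 so stratified reports aggregate cleanly. Length
stratification uses strict `>` cutoffs. A length-weighted variant
(each sequence weighted by its bp length) exists to quantify how the two
conventions diverge when one very long sequence is classified correctly
and many short ones are not; count-based metrics are the package's
default because short contigs dominate real assemblies.

The precision-recall curve sweeps the threshold over the distinct scores
descending and reports the step-wise area Σ (R_i − R_{i−1})·P_i (average
precision). The step rule is used instead of trapezoidal interpolation
because linear interpolation in PR space is optimistic; the tests
cross-check the area against scikit-learn's `average_precision_score`.

## Synthetic data

The generator stands in for curated plasmid/chromosome reference
databases and for read simulation + assembly, neither of which this
package performs.

- **Class sources** are order-1 Markov chains. Their log-weights combine
  a GC shift of ±0.31·divergence (so at divergence 1 the classes sit at
  GC ≈ 0.65 vs 0.35, a strongly separated pair; at divergence 0 both
  collapse to the uniform i.i.d. source) with a fixed class-specific
  dinucleotide signature scaled by the same divergence. The signature
  tables are generated once from fixed seeds, making the sources
  canonical objects rather than per-run draws.
- **Reference sets** (`make_benchmark_refs`) draw per-reference lengths
  log-uniform; defaults are 40 plasmids of 0.5–54 kb and 10 chromosomes
  of 10–140 kb. These echo real databases (plasmid median ≈ 54 kb,
  chromosome median ≈ 3.7 Mb) scaled for desk use — plasmids 10×
  shorter, chromosomes 100× — a deliberate compromise that preserves
  "chromosomes ≫ plasmids" while keeping the 10 kb bin trainable;
  consequently the 100 kb and 500 kb bins are exercised only through the
  depth-count arithmetic and the missing-bin fallback, not end to end.
- **Communities** (`simulate_community`): genome relative abundances are
  exp(N(0, σ²)) normalized to sum to 1 (σ default 1; the distribution's
  parameters are a modeling choice, config-exposed). Each plasmid is
  attached to a uniform random genome and draws an integer copy number
  from a geometric distribution on {1, 2, …} with success parameter
  p = min(1, log10(L)/7): expected copy number 1/p is non-increasing in
  plasmid length and locks to exactly 1 at 10 Mb. The logarithm is base
  10 (config-overridable): with a natural log every plasmid above ~1.1 kb
  would already have p = 1, defeating the intent that short plasmids can
  be multi-copy, whereas base 10 keeps p < 1 up to 10 Mb.
- **Contig-like fragments** (`fragment_community`) are drawn with
  expected counts proportional to abundance × copy number × source
  length and log-uniform lengths (default 200 bp – 50 kb, clamped to the
  source), mimicking the short-skewed length distribution of assembled
  metagenome contigs. This replaces read simulation and assembly
  entirely, which is acceptable because the classifier consumes
  sequences, not reads: what the synthetic route does *not* exercise is
  assembly artifacts (chimeras, fragmented repeats), shared backbone
  sequence between real plasmids and chromosomes, and the much weaker
  compositional separation of real genomes — so passing benchmarks here
  demonstrates correctness of the machinery, not real-data accuracy.

## Benchmarks and problem sizes

`plasq.benchmarks` packages four end-to-end studies used by both the
test suite and `scripts/acceptance.py`, with sizes chosen to run in
seconds on one CPU while keeping the statistics meaningful:

- `heldout_f1`: default references, divergence 0.8, 500 fragments per
  class per bin, 25% of references held out; 300 evaluation fragments
  per class at 1 kb and (when the held-out sets allow) 10 kb.
- `null_symmetry`: divergence 0; 400 training and 2000 test fragments
  per class of 1 kb, drawn directly from the source so test fragments
  are independent and the balanced-accuracy null is exactly binomial.
- `length_trend`: divergence 0.3 (mild, so the short-fragment task is
  genuinely hard), 400 training / 200 test fragments per class at 200 bp,
  1 kb and 10 kb; F1 rises toward 1 with fragment length.
- `community_benchmark`: a 10-genome community carrying 15 plasmids of
  0.5–20 kb, 1000 contigs; reports PR area, F1 above 1 kb, and the
  plasmid fraction (realistically well below the chromosome fraction).

## Numerical and degenerate-input choices

- Probabilities are written with 4 decimals for diffable, byte-stable
  output files; parallel classification is restricted to distributing
  independent per-sequence work, so results are bit-identical for any
  worker count.
- Model archives (`.npz`) store weights, intercepts, k range, boundaries,
  the feature-layout signature and a format version; loading verifies
  version and signature and turns any archive corruption into a clear
  error rather than a silent misread.
- Fragments containing ambiguous bases are kept (the featurizer skips
  the affected windows); fragments with more than `max_ambiguous_frac`
  (default 0.5) ambiguous bases are redrawn, with a retry bound so
  pathological references cannot loop forever.

## Known limitations

- Composition-based classification inherently confuses plasmids and
  chromosomes that share composition (e.g. recently transferred
  megaplasmids); the synthetic benchmarks do not model this.
- The 100 kb and 500 kb bins are validated structurally but not trained
  in the default benchmarks (no synthetic plasmid is that long).
- No gzip transparency, no FASTQ, no taxonomy-aware splitting, no
  duplicate-reference deduplication beyond id collisions.
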