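# Methods

## Profiles and the codec

A k-mer profile is a dense vector of `4^k` counts indexed by the integer
code of each word. The base mapping is fixed to A=00, C=01, G=10, T=11,
big-endian (first base most significant). Under this mapping complementation
is bitwise inversion of each 2-bit field, so the reverse complement of a
code is field-reversal of `code XOR (4^k − 1)` — constant time per word,
vectorizable over the whole code range. Any mapping with this property
would do; this one is normative for the package and recorded in the profile
container header (`encoding` attribute). k is capped at 15 so codes fit in
32-bit arithmetic and the dense vector stays addressable; analyses of
genomic data typically use k = 12, metagenome comparisons k = 10.

Counting slides a window of size k along each record. Windows containing
any non-ACGT character contribute nothing: each record is split into
maximal ACGT-only fragments, and a fragment of length L ≥ k contributes
exactly L − k + 1 windows. Skipping (rather than imputing) ambiguity codes
avoids inventing counts and keeps the codec's alphabet strict. Counts are
64-bit unsigned integers during counting; transforms may turn them into
non-negative reals. The dense representation (up to `4^12 ≈ 1.7×10^7`
entries, ~134 MB as uint64) was chosen over sparse because every transform
below operates on contiguous blocks in code order.

No strand canonicalization happens during counting: reads are counted as
given. Strand symmetry is only ever introduced by the explicit `balance`
transform, which keeps the strand-balance statistic meaningful.

## Profile algebra

* `merge` — element-wise sum (paired-end mates are merged before analysis).
* `shrink` — projection k → m < k by repeatedly summing blocks of 4 codes
  sharing a (k−1)-prefix. Totals are conserved, but note the boundary
  effect: a read of length L has L − k + 1 windows at size k and L − m + 1
  at size m, so a shrunk profile undercounts exactly one terminal window
  per read and per collapsed level relative to recounting — large
  deviations from the counted k progressively distort frequencies.
* `balance` — `new[w] = c[w] + c[rc(w)]`. Palindromic words are doubled:
  treating the self-pair like every other pair keeps the rule linear
  (`balance(balance(p)) = 2·balance(p)`) and makes the output an exact
  fixed point of the symmetry check. The alternative (leaving palindromes
  untouched) would make the transform non-linear for no analytical gain.
* `shuffle` — seeded permutation of the full vector including zeros, so the
  entire count distribution (nullomer mass included) is preserved.

## The multiset distance

`D(x, y) = Σ_{i∈S} f(x_i, y_i) / (|S| + 1)` with
`S = {i : x_i ≠ 0 or y_i ≠ 0}` and default
`f(x, y) = |x−y| / ((x+1)(y+1))`. Restricting the sum to S makes the
statistic independent of words absent from both datasets (otherwise the
overwhelming number of shared nullomers at large k would dilute every
comparison identically); the `+1` in the denominator guards the empty set
and keeps values strictly below 1. `f` is pluggable: any symmetric
non-negative function with `f(x,x) = 0` gives a valid dissimilarity;
absolute values depend on the choice, orderings are generally stable.
Accumulation is in fixed index order, so results are bit-reproducible on
one platform.

**Strand balance** applies the same distance to the two halves of one
profile: positions `w < rc(w)` form the forward vector, their mirrors the
reverse vector. Palindromes are excluded — a self-pair contributes
`f(c,c) = 0` to the numerator but would inflate `|S|`, diluting a statistic
that is meant to be purely about strand asymmetry. The statistic is 0
exactly when `c[w] = c[rc(w)]` for every non-palindromic w.

## Smoothing and scaling

`scale_pair` multiplies the smaller-total profile by
`larger_total / smaller_total` (exact ratio applied in floating point, no
rounding back). Scaling up rather than down preserves the resolution of the
deeper library. Scaling removes uniform multiplicative depth differences
exactly — duplicating every read n times changes nothing after scaling —
but cannot help with k-mers a shallow library missed entirely.

`smooth_pair` addresses those. It is defined bottom-up over the quartary
prefix tree: starting from singleton blocks at level k, every group of 4
sibling blocks whose members are all fully collapsed merges — in both
profiles — when the summary of its 4 block totals is ≤ threshold in
*either* profile. The merged group's total is stored at the
lexicographically first code of its prefix block (any fixed carrier
convention works; this one is stable and easy to test), and merging
iterates upward only through newly merged groups, stopping at word length 1
so a profile is never collapsed to a single bin. Design choices worth
stating explicitly:

* **Bottom-up, not top-down.** A top-down subtree test with the default
  min/0 policy would let a single nullomer anywhere collapse the entire
  profile at the root; bottom-up merging collapses exactly the weak
  neighbourhoods and nothing else.
* **OR across the pair.** A block weak in either library is merged in both,
  keeping the two block partitions identical so positions remain
  comparable for the distance.
* **Default policy min ≤ 0** merges precisely the groups containing an
  absent word — the words most sensitive to library size.
* The operation conserves per-profile totals, is idempotent for a fixed
  policy, and for the min summary a higher threshold never produces a finer
  partition.

The canonical pairwise order is balance → smooth → scale: smoothing must
see the raw integer count structure, and scaling last equalizes areas on
the final block structure. The all-vs-all `distance_matrix` runs this
pipeline on fresh copies per pair; transforms never mutate inputs or leak
across pairs.

## Synthetic data

The generator module stands in for real datasets with the simplest models
that preserve the statistics the method reads:

* `random_genome(length, gc_fraction, seed)` — i.i.d. bases; GC split
  evenly between G and C.
* `mutate_sequence(seq, divergence=0.1, seed)` — substitutes the stated
  fraction of positions with a different base, emulating closely related
  species at ~90% identity (real related bacterial genomes run 85–95%).
* `build_mixture` — whole-genome copies at integer copy numbers; the
  profile of a mixture is exactly the integer combination of the genome
  profiles, which serves as the oracle in tests.
* `simulate_reads` — uniform start positions (length-weighted across
  sources), strand chosen per read with configurable probability (0.5 =
  unbiased library, 0 = fully strand-biased), i.i.d. substitution errors.
  Paired mode emits the opposite-strand mate at the far end of a fixed
  insert.
* `permute_sequence` / `repetitive_sequence` — composition-preserving
  shuffles, and repeat-structured sequences (diverged copies of one unit
  interleaved with random spacers) whose k-mer structure a permutation
  destroys.

What these fixtures do *not* model: indels, quality-correlated error
clouds, real abundance distributions, GC-coverage bias, real homology
structure. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the statistics (depth robustness, mixture
geometry, balance curves), not quantitative agreement with any particular
real cohort.

## Study sizes and defaults in the acceptance experiments

All experiment sizes were fixed once, from first principles, and are the
package's defaults:

* **Mixture geometry** — three 50 kb genomes (two at 90% identity),
  mixtures 6:0:0 / 0:6:0 / 0:0:6 / 3:3:0 / 2:2:2, k = 10, plain scaled
  comparison. Every mixture holds six whole-genome copies, so totals are
  equal and scaling is a near-no-op; smoothing is deliberately *not*
  applied here, because with one unrelated genome it systematically
  stretches the even mixture's distance to the unrelated pure set (the
  related pair shares smoothed neighbourhoods), distorting the central
  geometry this experiment measures.
* **Depth robustness** — one 20 kb genome, 100 bp reads at 1× (200 reads)
  and 5× (1000 reads), k = 8 (the genome covers ~30% of 8-mer space, so
  depth-driven nullomers dominate the raw distance, which is the effect
  smoothing is designed to absorb).
* **k-scan** — a 20 kb repeat-structured sequence vs 10 permutation
  controls, k = 1..11. The distance is exactly 0 at k = 1 (composition is
  preserved), rises as k captures structure, and levels off (≈0.3% change
  between k = 10 and 11 at this scale).
* **Strand balance** — 20 kb genome, depths 250–4000 reads, k = 6. The
  choice 4^k ≪ genome length matters: an i.i.d. genome is then nearly
  strand-symmetric on its own, so single-strand sampling shows a positive
  balance falling with depth toward the genome's small residual asymmetry,
  while fair sampling falls toward 0. At k with 4^k above the genome size
  the single strand shares almost no reverse-complement words with itself
  and the single-strand balance instead rises toward 1 with depth — a
  regime change worth knowing when interpreting balance values for small
  genomes or amplicons.

## Numerical and degenerate-input choices

* Distances accumulate in float64 in index order; matrices are written at
  9 significant digits and round-trip to < 1e−8.
* `scale_pair` rejects zero-total profiles; `multiset_distance` of two
  all-zero profiles is defined as 0.
* `spectrum` rejects non-integral (scaled) counts rather than silently
  binning them.
* Records shorter than k, and empty FASTA files, are valid inputs that
  contribute nothing.
* Profile containers are HDF5 (`format = "kmer-profile-v1"`, one dataset
  per profile with `k` and `label` attributes); integer counts round-trip
  exactly. The schema is this package's own.

## Known limitations

* Dense vectors make k > 15 impractical; no disk-backed or probabilistic
  counting (minimizers, counting filters) is provided.
* The multiset distance is a dissimilarity, not a metric (no triangle
  inequality is claimed), and its absolute scale depends on f and on the
  transform options; compare only values produced with identical options.
* Smoothing assumes integer counts; apply it before any scaling.
* Downstream analyses (clustering, ordination) are out of scope — the
  package emits labelled distance matrices for standard tools.
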