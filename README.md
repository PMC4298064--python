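# kmerprof

Alignment-free analysis of DNA sequencing data through k-mer frequency
profiles: reference-free quality control, library comparison and complexity
assessment for NGS datasets (reads or assembled sequences), including
metagenomes where no single reference exists.

**Who it is for.** Anyone who needs to compare sequencing libraries — spot
outlier samples, contamination, strand bias, excessive duplication, or
resolve the relatedness of metagenome samples — without aligning a read or
choosing a reference genome.

## The method

A *k-mer profile* of a dataset is the vector of occurrence counts
`c = (c_w)` over all `4^k` DNA words `w` of length k, counted by a sliding
window (windows containing ambiguity codes are skipped; windows never span
record boundaries). Words are encoded in 2 bits per base (A=00, C=01, G=10,
T=11), so the reverse complement of a code is a constant-time bit
operation.

The dissimilarity between two profiles `x`, `y` is a **multiset distance**

```
D(x, y) = ( Σ_{i ∈ S} f(x_i, y_i) ) / ( |S| + 1 ),
S = { i : x_i ≠ 0 or y_i ≠ 0 },
f(x, y) = |x − y| / ((x + 1)(y + 1))
```

`f` is symmetric, zero on equal counts and bounded below 1; it weights
discrepancies most heavily where counts are small — exactly the rare-k-mer
regime where library artefacts (chimeras, errors, contamination) appear.

Profiles of libraries sequenced at different depths are made comparable by
two transforms, applied pairwise in a fixed order:

* **dynamic smoothing** — wherever the counts of 4 sibling k-mers (sharing
  a (k−1)-prefix) fall below a threshold under a summary function (default:
  minimum ≤ 0, i.e. the group contains an absent word) in *either* profile,
  the group is merged to the shorter word length in *both* profiles,
  bottom-up and repeatedly; totals are conserved.
* **scaling** — the profile with the smaller total is multiplied up so both
  totals ("areas under the curve") match.

Two single-profile statistics complete the toolkit: the **k-mer spectrum**
(how many k-mers occur c times; its modality reflects genome complexity)
and the **strand balance** (the multiset distance between the sub-profile
of k-mers and that of their reverse complements; 0 = both strands covered
evenly).

## Worked example

Two simulated read sets of the same 20 kb genome at 1× and 5× coverage
(`examples/02_transforms_and_distance.py`):

```
no transform:      0.4680
scale only:        0.4565
smooth then scale: 0.0527
```

Both libraries sample the same genome, so a depth-robust comparison should
report a small distance. The raw and globally scaled distances are
dominated by the k-mers the shallow library happened to miss; smoothing
collapses those weakly covered groups in both profiles before scaling and
recovers a roughly ten-fold smaller distance.

Mixture composition is read off profile distances the same way
(`examples/03_metagenome_mixtures.py`): with three synthetic genomes (two
at ~90% identity) mixed at copy numbers 6:0:0 … 2:2:2, the even 2:2:2
mixture is nearly equidistant from the three pure mixtures
(max/min = 1.074) while 3:3:0 sits between its two constituent pure sets.
The other examples cover profile basics, choosing k with permutation
controls, and strand-balance depth curves — each prints its numbers with a
note on what they mean.

## Command line

The same workflow is available as a thin CLI:

```bash
kmerprof count reads.fa profiles.h5 --k 12 --name sample1
kmerprof info profiles.h5
kmerprof matrix profiles.h5 --smooth --scale --out distances.tsv
kmerprof showbalance profiles.h5
```

Subcommands: `count`, `merge`, `shrink`, `balance`, `shuffle`, `info`,
`spectrum`, `showbalance`, `distance`, `matrix`, `convert` (FASTQ→FASTA),
`simulate`, `scan-k`. Profiles live in an HDF5 container (several per
file); matrices are labelled TSV.

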