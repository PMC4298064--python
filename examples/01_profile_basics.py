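"""Build a k-mer profile from sequences and inspect it.

Counts every length-k window of a small read set, prints summary statistics
and the k-mer spectrum, then shrinks the profile to a smaller word length.
"""

import kmerprof as kp

reads = [
    kp.SequenceRecord("read1", "ACGTACGTACGT"),
    kp.SequenceRecord("read2", "ACGTTTTACGAA"),
    kp.SequenceRecord("read3", "GGGNACGT"),  # the window over N is skipped
]

profile = kp.count(reads, k=4, label="demo")
stats = kp.info(profile)
print(f"k={stats['k']}  total windows={stats['total']:.0f}  "
      f"distinct k-mers={stats['non_zero']}  nullomers={stats['nullomers']}")
# total = sum over reads of (L - k + 1) ACGT-only windows; nullomers are the
# 4^k words never observed — their number reflects how much of sequence
# space the data covers.

print("spectrum (frequency -> number of k-mers):", kp.spectrum(profile))
# a long tail of frequency-1 k-mers in real data often marks sequencing
# errors or library chimeras.

shrunk = kp.shrink(profile, 2)
print(f"shrunk to k=2: total={shrunk.total:.0f} (conserved), "
      f"distinct={shrunk.non_zero}")
# shrinking sums the 4 counts sharing each (k-1)-prefix; it reuses an
# existing profile at a smaller k without reprocessing the reads.
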