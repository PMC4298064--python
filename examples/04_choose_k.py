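"""Choose a profiling word length k with permutation controls.

Compares a repeat-structured sequence against composition-preserving random
permutations of itself across a range of k. The permutations destroy all
word structure beyond single-base composition, so the distance to them
measures how much real structure a k-mer profile of each size captures.
"""

import kmerprof as kp

sequence = kp.repetitive_sequence(n_units=20, unit_length=500,
                                  spacer_length=500, seed=7)
table = kp.scan_k(sequence, k_min=1, k_max=11, n_permutations=10, seed=7)
print(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
# At k=1 the distance is exactly 0: permutation preserves base composition.
# The curve rises as larger k captures more structure, then levels off —
# the smallest k on the plateau separates real structure from permuted
# noise without wasting resolution, and is a good profiling word length.

means = table.mean_distance.to_numpy()
print(f"\nrelative change between k={table.k.iloc[-2]} and "
      f"k={table.k.iloc[-1]}: {abs(means[-1] - means[-2]) / means[-2]:.2%}")
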