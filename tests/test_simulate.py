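"""Synthetic genomes, mixtures, reads and permutation controls."""

import numpy as np
import pytest

from kmerprof import (
    MixtureSpec,
    ReadSimSpec,
    SequenceRecord,
    build_mixture,
    count,
    multiset_distance,
    mutate_sequence,
    permute_sequence,
    random_genome,
    repetitive_sequence,
    scan_k,
    simulate_reads,
    strand_balance,
)


class TestRandomGenome:
    def test_zero_gc_is_at_only(self):
        assert set(random_genome(500, gc_fraction=0, seed=1)) <= {"A", "T"}

    def test_seed_reproducible(self):
        assert random_genome(200, seed=5) == random_genome(200, seed=5)
        assert random_genome(200, seed=5) != random_genome(200, seed=6)

    def test_gc_concentration(self):
        genome = random_genome(100_000, gc_fraction=0.5, seed=2)
        gc = sum(genome.count(b) for b in "GC") / len(genome)
        assert abs(gc - 0.5) < 0.01  # ~6 sd of Binomial(1e5, 0.5)

    @pytest.mark.parametrize("length, gc", [(0, 0.5), (10, -0.1), (10, 1.5)])
    def test_invalid_parameters(self, length, gc):
        with pytest.raises(ValueError):
            random_genome(length, gc)


class TestMutateSequence:
    def test_divergence_fraction(self):
        genome = random_genome(50_000, seed=3)
        mutated = mutate_sequence(genome, 0.1, seed=4)
        identity = sum(a == b for a, b in zip(genome, mutated)) / len(genome)
        assert identity == pytest.approx(0.9, abs=0.01)

    def test_zero_divergence_identity(self):
        genome = random_genome(100, seed=1)
        assert mutate_sequence(genome, 0.0, seed=2) == genome


class TestPermuteSequence:
    def test_composition_preserved(self):
        genome = random_genome(1000, gc_fraction=0.3, seed=7)
        permuted = permute_sequence(genome, seed=8)
        assert sorted(permuted) == sorted(genome)
        assert len(permuted) == len(genome)

    def test_mononucleotide_profile_conserved_structure_destroyed(self):
        sequence = repetitive_sequence(n_units=5, seed=9)
        permuted = permute_sequence(sequence, seed=10)
        record = [SequenceRecord("s", sequence)]
        shuffled = [SequenceRecord("s", permuted)]
        assert np.array_equal(count(record, 1).counts, count(shuffled, 1).counts)
        assert not np.array_equal(count(record, 6).counts, count(shuffled, 6).counts)


class TestBuildMixture:
    def make_genomes(self):
        return [SequenceRecord(f"g{i}", random_genome(2000, seed=i)) for i in range(3)]

    def test_record_count_and_length(self):
        genomes = self.make_genomes()
        records = build_mixture(MixtureSpec(genomes, (2, 2, 2)))
        assert len(records) == 6
        assert sum(len(r.sequence) for r in records) == 3 * 2 * 2000

    def test_profile_is_linear_combination(self):
        """Mixture profile equals the integer combination of genome profiles."""
        genomes = self.make_genomes()
        copies = (3, 1, 2)
        mixture_profile = count(build_mixture(MixtureSpec(genomes, copies)), 5)
        expected = sum(
            c * count([g], 5).counts.astype(np.int64) for g, c in zip(genomes, copies)
        )
        assert np.array_equal(mixture_profile.counts.astype(np.int64), expected)

    def test_all_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(self.make_genomes(), (0, 0, 0))


class TestSimulateReads:
    def test_read_count_length_and_determinism(self):
        genome = random_genome(5000, seed=11)
        spec = ReadSimSpec(read_length=80, n_reads=50, seed=12)
        reads = list(simulate_reads(genome, spec))
        assert len(reads) == 50
        assert all(len(r.sequence) == 80 for r in reads)
        assert [r.sequence for r in simulate_reads(genome, spec)] == [
            r.sequence for r in reads
        ]

    def test_error_free_forward_reads_introduce_no_novel_kmers(self):
        genome = random_genome(5000, seed=13)
        spec = ReadSimSpec(read_length=100, n_reads=200, error_rate=0.0,
                           reverse_probability=0.0, seed=14)
        read_profile = count(simulate_reads(genome, spec), 8)
        genome_profile = count([SequenceRecord("g", genome)], 8)
        novel = (read_profile.counts > 0) & (genome_profile.counts == 0)
        assert not novel.any()

    def test_errors_increase_distance_to_source(self):
        """Substitution errors introduce rare artificial k-mers, pushing the
        read profile away from the source genome profile."""
        genome = random_genome(20_000, seed=15)
        genome_profile = count([SequenceRecord("g", genome)], 8)

        def dist(error_rate):
            spec = ReadSimSpec(read_length=100, n_reads=400,
                               error_rate=error_rate, reverse_probability=0.0, seed=16)
            return multiset_distance(count(simulate_reads(genome, spec), 8), genome_profile)

        assert dist(0.3) > dist(0.0)

    def test_paired_mode_emits_opposite_strand_mates(self):
        genome = random_genome(3000, seed=17)
        spec = ReadSimSpec(read_length=50, n_reads=30, paired=True,
                           insert_size=200, seed=18)
        reads = list(simulate_reads(genome, spec))
        assert len(reads) == 60
        # every mate subsequence must occur in the genome on one strand
        from kmerprof.simulate import reverse_complement_str

        rc = reverse_complement_str(genome)
        assert all(r.sequence in genome or r.sequence in rc for r in reads)

    def test_short_source_rejected(self):
        with pytest.raises(ValueError):
            list(simulate_reads("ACGT", ReadSimSpec(read_length=10, n_reads=1)))

    def test_deeper_sampling_of_strand_symmetric_source_lowers_balance(self):
        """Forward-only reads from a genome plus its reverse complement are
        a strand-symmetric source: the balance statistic shrinks with depth."""
        from kmerprof.simulate import reverse_complement_str

        genome = random_genome(10_000, seed=19)
        source = [
            SequenceRecord("fwd", genome),
            SequenceRecord("rev", reverse_complement_str(genome)),
        ]
        balances = []
        for n_reads, seed in ((200, 20), (2000, 21)):
            spec = ReadSimSpec(read_length=100, n_reads=n_reads,
                               reverse_probability=0.0, seed=seed)
            balances.append(strand_balance(count(simulate_reads(source, spec), 6)))
        assert balances[1] < balances[0]


class TestScanK:
    def test_permutation_controls_indistinguishable_at_k1(self):
        sequence = repetitive_sequence(n_units=5, seed=22)
        table = scan_k(sequence, 1, 3, n_permutations=3, seed=23)
        assert list(table.columns) == ["k", "mean_distance", "sd_distance"]
        assert table.loc[table.k == 1, "mean_distance"].item() < 1e-9
        assert table.mean_distance.is_monotonic_increasing

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            scan_k("ACGT" * 100, 3, 2)
        with pytest.raises(ValueError):
            scan_k("ACGT" * 100, 1, 3, n_permutations=1)
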