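import numpy as np
import pytest

from clipscan.realigner import ReferenceIndex
from clipscan.simulator import (
    MapperEmulator,
    SimulationConfig,
    emulate_mapper,
    emulate_mapper_paired,
    even_sizes,
    place_indels,
    random_reference,
    simulate_reads,
)
from conftest import plant_indel


class TestPlaceIndels:
    def test_single_deletion_length_bookkeeping(self):
        reference = random_reference(20_000, seed=1, name="chr1")
        cfg = SimulationConfig(n_del=1, n_ins=0, size_min=10, size_max=10, seed=2)
        mutated, truth = place_indels(reference, cfg)
        assert len(mutated["chr1"]) == 20_000 - 10
        assert len(truth) == 1 and truth[0].type == "DEL" and truth[0].size == 10

    def test_single_insertion_length_bookkeeping(self):
        reference = random_reference(20_000, seed=1, name="chr1")
        cfg = SimulationConfig(n_del=0, n_ins=1, size_min=137, size_max=137, seed=2)
        mutated, truth = place_indels(reference, cfg)
        assert len(mutated["chr1"]) == 20_000 + 137
        assert len(truth[0].inserted_seq) == 137

    def test_conservation_identity_with_many_events(self):
        reference = random_reference(200_000, seed=3, name="chr1")
        cfg = SimulationConfig(n_del=20, n_ins=20, seed=4)
        mutated, truth = place_indels(reference, cfg)
        delta = sum(t.size for t in truth if t.type == "INS") - sum(
            t.size for t in truth if t.type == "DEL"
        )
        assert len(mutated["chr1"]) == 200_000 + delta

    def test_truth_records_never_overlap(self):
        reference = random_reference(300_000, seed=5, name="chr1")
        cfg = SimulationConfig(n_del=50, n_ins=50, seed=6)
        _, truth = place_indels(reference, cfg)
        spans = sorted((t.start, max(t.end, t.start + 1)) for t in truth)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_fixed_seed_is_deterministic(self):
        reference = random_reference(100_000, seed=7, name="chr1")
        cfg = SimulationConfig(n_del=10, n_ins=10, seed=8)
        a = place_indels(reference, cfg)
        b = place_indels(reference, cfg)
        assert a == b

    def test_n_runs_excluded_from_eligible_bins(self):
        seq = random_reference(30_000, seed=9, name="chr1")["chr1"]
        # poison every second 1-kb bin with an N
        poisoned = "".join(
            seq[i : i + 1000] if (i // 1000) % 2 == 0 else "N" + seq[i + 1 : i + 1000]
            for i in range(0, 30_000, 1000)
        )
        reference = {"chr1": poisoned}
        cfg = SimulationConfig(n_del=10, n_ins=5, seed=10)
        _, truth = place_indels(reference, cfg)
        for t in truth:
            assert (t.start // 1000) % 2 == 0

    def test_too_few_bins_raises(self):
        reference = random_reference(5_000, seed=11, name="chr1")
        with pytest.raises(ValueError, match="bins"):
            place_indels(reference, SimulationConfig(n_del=10, n_ins=10, seed=1))

    def test_even_sizes_cover_full_range(self):
        assert even_sizes(1000, 1, 1000) == list(range(1, 1001))
        fifty = even_sizes(50, 1, 1000)
        assert fifty[0] == 1 and fifty[-1] == 1000 and len(fifty) == 50
        assert fifty == sorted(fifty)


class TestSimulateReads:
    def test_pair_count_formula(self):
        genome = random_reference(100_000, seed=12, name="chr1")
        cfg = SimulationConfig(coverage=10, read_len=100, seed=13)
        reads1, reads2 = simulate_reads(genome, cfg)
        assert len(reads1) == len(reads2) == 5000

    def test_error_free_reads_are_fragment_substrings(self):
        genome = random_reference(50_000, seed=14, name="chr1")
        cfg = SimulationConfig(coverage=2, base_error=0.0, mut_rate=0.0, seed=15)
        reads1, reads2 = simulate_reads(genome, cfg)
        seq = genome["chr1"]
        from clipscan.alignment_core import revcomp

        for name, s, q in reads1[:50]:
            assert s in seq
        for name, s, q in reads2[:50]:
            assert revcomp(s) in seq

    def test_fixed_seed_is_deterministic(self):
        genome = random_reference(30_000, seed=16, name="chr1")
        cfg = SimulationConfig(coverage=3, seed=17)
        assert simulate_reads(genome, cfg) == simulate_reads(genome, cfg)

    def test_error_positions_marked_low_quality(self):
        genome = random_reference(30_000, seed=18, name="chr1")
        cfg = SimulationConfig(coverage=2, base_error=0.05, mut_rate=0.0, seed=19)
        reads1, _ = simulate_reads(genome, cfg)
        seq = genome["chr1"]
        checked = 0
        for name, s, q in reads1:
            start = int(name.split("_")[1])
            true = seq[start : start + len(s)]
            for i, (a, b) in enumerate(zip(s, true)):
                if a != b:
                    assert q[i] < 33 + 20  # below the clip-quality threshold
                    checked += 1
        assert checked > 0


class TestEmulateMapper:
    def test_clean_reads_map_full_length(self):
        reference = random_reference(30_000, seed=20, name="chr1")
        cfg = SimulationConfig(coverage=2, base_error=0.0, mut_rate=0.0, seed=21)
        reads1, reads2 = simulate_reads(reference, cfg)  # genome == reference
        records = emulate_mapper_paired(reads1, reads2, reference)
        assert all(not r.is_unmapped for r in records)
        assert all(str(r.cigar) == "100M" for r in records)
        # placement is exact on an indel-free genome
        for r in records:
            start, end = (int(x) for x in r.name.split("_")[1:3])
            assert r.pos in (start, end - 100)

    def test_small_deletion_is_aligned_through(self):
        reference = random_reference(20_000, seed=22, name="chr1")
        mutated, truth = plant_indel(reference, "DEL", 5, 10_000)
        read = mutated["chr1"][9_950 : 10_050]
        (rec,) = emulate_mapper([("r", read, b"?" * 100)], reference)
        assert "5D" in str(rec.cigar)

    def test_large_deletion_becomes_soft_clip(self):
        reference = random_reference(20_000, seed=23, name="chr1")
        mutated, truth = plant_indel(reference, "DEL", 300, 10_000)
        read = mutated["chr1"][9_950 : 10_050]
        (rec,) = emulate_mapper([("r", read, b"?" * 100)], reference)
        cig = rec.cigar
        assert cig.clipped_length >= 20
        assert max(ln for ln, op in cig if op == "M") >= 40

    def test_reverse_strand_reads_flagged_and_stored_forward(self):
        reference = random_reference(20_000, seed=24, name="chr1")
        from clipscan.alignment_core import revcomp

        seq = reference["chr1"][4_000:4_100]
        (rec,) = emulate_mapper([("r", revcomp(seq), b"?" * 100)], reference)
        assert rec.is_reverse
        assert rec.seq == seq
        assert rec.pos == 4_000

    def test_foreign_read_is_unmapped(self):
        reference = random_reference(20_000, seed=25, name="chr1")
        rng = np.random.default_rng(26)
        read = "".join(rng.choice(list("ACGT"), size=100))
        (rec,) = emulate_mapper([("r", read, b"?" * 100)], reference)
        assert rec.is_unmapped

    def test_index_reuse_matches_fresh_index(self):
        reference = random_reference(20_000, seed=27, name="chr1")
        seq = reference["chr1"][1_000:1_100]
        index = ReferenceIndex(reference, k=16)
        (a,) = emulate_mapper([("r", seq, b"?" * 100)], reference, index=index)
        (b,) = emulate_mapper([("r", seq, b"?" * 100)], reference)
        assert (a.pos, str(a.cigar)) == (b.pos, str(b.cigar))
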