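import numpy as np
import pytest

from clipscan.caller import (
    CallerParams,
    call_variants,
    extract_indel_evidence,
    merge_vcfs,
    normalize_indel,
)
from clipscan.simulator import random_reference
from conftest import make_read


def brute_force_leftmost(chrom, pos, ref, alt, reference):
    """Enumeration oracle: all shift-equivalent representations, leftmost minimal.

    Two representations are equivalent when applying them to the reference
    produces the same haplotype string.
    """
    seq = reference[chrom]

    def apply(p, r, a):
        return seq[:p] + a + seq[p + len(r):]

    target = apply(pos, ref, alt)
    size = abs(len(ref) - len(alt))
    best = None
    for p in range(max(0, pos - 200), min(len(seq), pos + 200)):
        if len(ref) > len(alt):  # deletion: try every same-size deletion nearby
            for anchor_len in (1,):
                r = seq[p : p + size + 1]
                a = seq[p : p + 1]
                if len(r) == size + 1 and apply(p, r, a) == target:
                    best = (chrom, p, r, a)
                    break
        else:  # insertion of `size` bases at p
            want = target[p + 1 : p + 1 + size]
            r = seq[p : p + 1]
            a = r + want
            if r and apply(p, r, a) == target:
                best = (chrom, p, r, a)
        if best:
            return best
    return (chrom, pos, ref, alt)


class TestNormalizeIndel:
    def test_homopolymer_deletion_left_shifts(self):
        reference = {"chr1": "GGCAAATGG"}
        # deleting any single A in the AAA run is the same haplotype
        for anchor in (2, 3, 4):
            ref = reference["chr1"][anchor : anchor + 2]
            out = normalize_indel("chr1", anchor, ref, ref[0], reference)
            assert out == ("chr1", 2, "CA", "C")

    def test_non_repetitive_indel_unchanged_and_idempotent(self):
        reference = {"chr1": "GATTCGACGATA"}
        out = normalize_indel("chr1", 4, "CGA", "C", reference)
        assert out == ("chr1", 4, "CGA", "C")
        assert normalize_indel(*out, reference) == out

    def test_dinucleotide_insertion_left_shifts(self):
        reference = {"chr1": "CCATGTGTGCAA"}
        # inserting TG after any TG unit is equivalent; leftmost anchor is the A at 2
        out = normalize_indel("chr1", 8, "G", "GTG", reference)
        assert out == ("chr1", 2, "A", "ATG")

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_indel("chr1", 0, "TT", "T", {"chr1": "ACGT"})

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(55)
        reference = random_reference(3_000, seed=56, name="chr1")
        seq = reference["chr1"]
        for _ in range(300):
            pos = int(rng.integers(100, 2_800))
            size = int(rng.integers(1, 12))
            if rng.random() < 0.5:
                ref, alt = seq[pos : pos + size + 1], seq[pos]
            else:
                ins = "".join(rng.choice(list("ACGT"), size=size))
                ref = seq[pos]
                alt = ref + ins
            got = normalize_indel("chr1", pos, ref, alt, reference)
            assert got == brute_force_leftmost("chr1", pos, ref, alt, reference)


class TestExtractEvidence:
    def setup_method(self):
        self.reference = random_reference(3_000, seed=60, name="chr1")

    def _read(self, name, pos, cigar, seq_len):
        seq = self.reference["chr1"][pos : pos + seq_len]  # placeholder bases
        return make_read(name=name, seq=seq[:seq_len].ljust(seq_len, "A"),
                         cigar=cigar, pos=pos)

    def test_shared_deletion_aggregates_support(self):
        reads = [self._read(f"r{i}", 1000, "50M6D50M", 100) for i in range(10)]
        evidence = extract_indel_evidence(reads, self.reference)
        assert len(evidence) == 1
        ev = evidence[0]
        assert (ev.svtype, ev.size, ev.support) == ("DEL", 6, 10)
        # breakpoint at 1050 modulo left-alignment within a local repeat
        assert abs(ev.pos + 1 - 1050) <= 6

    def test_insertion_allele_comes_from_read(self):
        seq = self.reference["chr1"]
        ins = "GTCCATTGCAGGACCTTGGA"  # 20 bp
        read_seq = seq[500:540] + ins + seq[540:580]
        read = make_read(name="i1", seq=read_seq, cigar="40M20I40M", pos=500)
        (ev,) = extract_indel_evidence([read], self.reference)
        assert (ev.svtype, ev.size) == ("INS", 20)
        assert ins in ev.alt

    def test_no_indel_ops_gives_empty_evidence(self):
        reads = [self._read("r0", 100, "100M", 100), self._read("r1", 300, "30S70M", 100)]
        assert extract_indel_evidence(reads, self.reference) == []


class TestCallVariants:
    def setup_method(self):
        self.reference = random_reference(3_000, seed=61, name="chr1")
        self.params = CallerParams()

    def _del_reads(self, n, pos=1000, name_prefix="d"):
        seq = self.reference["chr1"]
        return [
            make_read(name=f"{name_prefix}{i}",
                      seq=(seq[pos:pos + 50] + seq[pos + 56:pos + 106]),
                      cigar="50M6D50M", pos=pos)
            for i in range(n)
        ]

    def test_min_support_filters(self):
        reads, _ = self._del_reads(2), None
        calls, _ = call_variants(reads, [], self.params, self.reference)
        assert calls == []

    def test_supported_call_passes_fraction_filter(self):
        support = self._del_reads(10)
        background = [
            make_read(name=f"b{i}", seq=self.reference["chr1"][900:1000],
                      cigar="100M", pos=900)
            for i in range(90)
        ]
        calls, _ = call_variants(support + background, [], self.params, self.reference)
        assert len(calls) == 1
        call = calls[0]
        assert (call.svtype, call.size, call.support, call.source) == ("DEL", 6, 10, "reads")
        assert call.support / call.depth >= 0.05

    def test_contig_branch_exempt_from_read_thresholds(self):
        seq = self.reference["chr1"]
        ins = "A" * 0 or "".join("ACGT"[(i * 7) % 4] for i in range(300))
        contig_seq = seq[800:900] + ins + seq[900:1000]
        contig = make_read(name="contig_1", seq=contig_seq, cigar="100M300I100M", pos=800)
        read_calls, contig_calls = call_variants([], [contig], self.params, self.reference)
        assert read_calls == []
        assert len(contig_calls) == 1
        assert (contig_calls[0].svtype, contig_calls[0].size, contig_calls[0].source) == (
            "INS", 300, "contigs",
        )

    def test_emitted_alleles_reconstruct_reference(self):
        calls, _ = call_variants(self._del_reads(5), [], self.params, self.reference)
        for call in calls:
            seq = self.reference[call.chrom]
            assert seq[call.pos - 1 : call.pos - 1 + len(call.ref)] == call.ref


class TestMergeVcfs:
    def _call(self, pos=100, ref="AC", alt="A", svtype="DEL", size=1,
              support=5, source="reads"):
        from clipscan.alignment_core import IndelCall

        return IndelCall("chr1", pos, ref, alt, svtype, size, support, 50, source)

    def test_identical_call_collapses_with_joint_source(self):
        a = self._call(source="reads", support=7)
        b = self._call(source="contigs", support=3)
        merged = merge_vcfs([a], [b])
        assert len(merged) == 1
        assert merged[0].source == "reads,contigs"
        assert merged[0].support == 7

    def test_disjoint_calls_concatenate_in_order(self):
        a = self._call(pos=100)
        b = self._call(pos=500, source="contigs")
        merged = merge_vcfs([a], [b])
        assert [c.pos for c in merged] == [100, 500]

    def test_same_locus_different_sizes_both_kept(self):
        a = self._call(pos=100, ref="AC", alt="A", size=1)
        b = self._call(pos=100, ref="ACG", alt="A", size=2, source="contigs")
        assert len(merge_vcfs([a], [b])) == 2

    def test_merge_is_idempotent(self):
        v = [self._call(pos=100), self._call(pos=300, ref="A", alt="AGG", svtype="INS", size=2)]
        assert merge_vcfs(v, v) == v

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_vcfs([self._call(pos=500), self._call(pos=100)], [])
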