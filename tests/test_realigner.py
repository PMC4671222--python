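import numpy as np
import pytest

from clipscan.alignment_core import parse_cigar
from clipscan.realigner import (
    PslHit,
    RealignerParams,
    ReferenceIndex,
    accept_hit,
    blat_score,
    gapped_align,
    identity,
    psl_to_cigar,
    realign_reads,
    replace_alignment,
)
from clipscan.simulator import random_reference
from conftest import make_read


def hit(blocks, matches=None, mismatches=0, q_gaps=0, t_gaps=0, strand="+", q_end=None):
    total = sum(b[2] for b in blocks)
    if matches is None:
        matches = total - mismatches
    return PslHit(
        strand=strand,
        q_start=blocks[0][0],
        q_end=q_end if q_end is not None else blocks[-1][0] + blocks[-1][2],
        t_name="chr1",
        blocks=tuple(blocks),
        matches=matches,
        mismatches=mismatches,
        q_gap_count=q_gaps,
        t_gap_count=t_gaps,
    )


class TestScoreIdentityAccept:
    @pytest.mark.parametrize(
        "matches,mm,qg,tg,expected",
        [(100, 0, 0, 0, 100), (50, 5, 0, 1, 44), (0, 0, 0, 0, 0)],
    )
    def test_blat_score(self, matches, mm, qg, tg, expected):
        h = hit([(0, 0, matches + mm)], matches=matches, mismatches=mm,
                q_gaps=qg, t_gaps=tg) if matches + mm else None
        if h is None:
            # degenerate empty alignment cannot be constructed as blocks;
            # score formula is checked on a minimal 1-column hit instead
            h = hit([(0, 0, 1)], matches=0, mismatches=1)
            assert blat_score(h) == -1
            return
        assert blat_score(h) == expected

    @pytest.mark.parametrize("matches,mm,expected", [(90, 10, 0.90), (77, 0, 1.0), (9, 1, 0.90)])
    def test_identity(self, matches, mm, expected):
        assert identity(hit([(0, 0, matches + mm)], matches=matches, mismatches=mm)) == pytest.approx(expected)

    def test_accept_boundaries_are_strict(self):
        params = RealignerParams()
        ok = hit([(0, 0, 31)])  # score 31, identity 1.0
        assert accept_hit([ok], params) is ok
        at_bar = hit([(0, 0, 30)])  # score 30 -> rejected (strict >)
        assert accept_hit([at_bar], params) is None
        low_id = hit([(0, 0, 100)], matches=90, mismatches=10)  # identity 0.90 -> rejected
        assert accept_hit([low_id], params) is None
        assert accept_hit([], params) is None


class TestPslToCigar:
    @pytest.mark.parametrize(
        "blocks,q_start,read_len,expected_pos,expected_cigar",
        [
            ([(0, 500, 100)], 0, 100, 500, "100M"),
            ([(10, 500, 90)], 10, 100, 500, "10S90M"),
            ([(0, 500, 50), (50, 750, 50)], 0, 100, 500, "50M200D50M"),
            ([(0, 500, 40), (60, 540, 40)], 0, 100, 500, "40M20I40M"),
            ([(5, 500, 40), (60, 545, 30)], 5, 100, 500, "5S40M15I5D30M10S"),
        ],
    )
    def test_examples(self, blocks, q_start, read_len, expected_pos, expected_cigar):
        h = hit(blocks)
        pos, cigar = psl_to_cigar(h, read_len)
        assert pos == expected_pos
        assert str(cigar) == expected_cigar

    def test_block_round_trip_randomized(self):
        """psl_to_cigar followed by CIGAR->block reconstruction is the identity."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            q = int(rng.integers(0, 20))
            t = int(rng.integers(0, 5000))
            blocks = []
            for _b in range(int(rng.integers(1, 5))):
                ln = int(rng.integers(1, 80))
                blocks.append((q, t, ln))
                q += ln + int(rng.integers(0, 30))
                t += ln + int(rng.integers(0, 300))
            # ensure last block abuts q_end to keep geometry consistent
            read_len = blocks[-1][0] + blocks[-1][2] + int(rng.integers(0, 15))
            h = hit(blocks)
            pos, cigar = psl_to_cigar(h, read_len)
            # reconstruct blocks by walking the CIGAR
            rq, rt = 0, pos
            rebuilt = []
            for ln, op in cigar:
                if op == "S":
                    rq += ln
                elif op == "M":
                    rebuilt.append((rq, rt, ln))
                    rq += ln
                    rt += ln
                elif op == "I":
                    rq += ln
                elif op == "D":
                    rt += ln
            # merge abutting blocks the same way the converter would
            merged = []
            for b in rebuilt:
                if merged and merged[-1][0] + merged[-1][2] == b[0] and merged[-1][1] + merged[-1][2] == b[1]:
                    prev = merged.pop()
                    merged.append((prev[0], prev[1], prev[2] + b[2]))
                else:
                    merged.append(b)
            assert tuple(merged) == h.blocks
            assert cigar.query_length == read_len

    def test_inconsistent_blocks_rejected(self):
        with pytest.raises(ValueError):
            PslHit("+", 0, 50, "chr1", ((0, 100, 30), (20, 90, 30)), 60, 0, 0, 0)


class TestGappedAlign:
    def test_exact_substring_single_block(self, small_reference, small_index):
        seq = small_reference["chr1"]
        query = seq[5000:5100]
        hits = gapped_align(query, small_reference, small_index)
        top = hits[0]
        assert top.strand == "+"
        assert top.blocks == ((0, 5000, 100),)
        assert top.mismatches == 0 and top.q_gap_count == 0 and top.t_gap_count == 0

    def test_constructed_deletion_has_exact_target_gap(self, small_reference, small_index):
        seq = small_reference["chr1"]
        a = 8000
        query = seq[a : a + 50] + seq[a + 250 : a + 300]
        top = gapped_align(query, small_reference, small_index)[0]
        assert len(top.blocks) == 2
        (q1, t1, l1), (q2, t2, l2) = top.blocks
        assert t2 - (t1 + l1) == 200
        assert q2 == q1 + l1  # contiguous in the query
        assert l1 + l2 == 100

    def test_random_query_is_not_accepted(self):
        params = RealignerParams()
        reference = random_reference(10_000, seed=5, name="chrR")
        index = ReferenceIndex(reference, k=16)
        rng = np.random.default_rng(99)
        for _ in range(10):
            query = "".join(rng.choice(list("ACGT"), size=100))
            hits = gapped_align(query, reference, index, params=params)
            assert accept_hit(hits, params) is None

    @pytest.mark.parametrize("d", [30, 100, 500, 1000])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_deletion_yields_exact_d_run(self, d, seed):
        reference = random_reference(20_000, seed=200 + seed, name="chr1")
        seq = reference["chr1"]
        index = ReferenceIndex(reference, k=16)
        start = 9_000
        mutated = seq[:start] + seq[start + d :]
        # 100-bp read clipped at the breakpoint (50/50 split)
        query = mutated[start - 50 : start + 50]
        top = gapped_align(query, reference, index)[0]
        pos, cigar = psl_to_cigar(top, len(query))
        d_runs = [ln for ln, op in cigar if op == "D"]
        assert d_runs == [d]


class TestReplaceAlignment:
    def test_replacement_updates_coordinates_and_tags(self, small_reference, small_index):
        seq = small_reference["chr1"]
        a = 8000
        query = seq[a : a + 50] + seq[a + 250 : a + 300]
        read = make_read(name="r", seq=query, cigar="50M50S", pos=a, mapq=60)
        top = gapped_align(query, small_reference, small_index)[0]
        new = replace_alignment(read, top)
        assert new is not read
        assert new.pos == a
        assert str(new.cigar) == "50M200D50M"
        assert new.tags["OA"].startswith(f"chr1,{a + 1},+,50M50S")
        new.check_query_consumption()

    def test_identical_alignment_is_idempotent_modulo_tag(self, small_reference, small_index):
        seq = small_reference["chr1"]
        query = seq[5000:5100]
        read = make_read(name="r", seq=query, cigar="100M", pos=5000)
        top = gapped_align(query, small_reference, small_index)[0]
        new = replace_alignment(read, top)
        assert (new.chrom, new.pos, str(new.cigar)) == ("chr1", 5000, "100M")
        assert "OA" in new.tags

    def test_realign_reads_reports_acceptances(self, small_reference, small_index):
        seq = small_reference["chr1"]
        a = 6000
        query = seq[a : a + 50] + seq[a + 150 : a + 200]
        reads = [make_read(name="r1", seq=query, cigar="50M50S", pos=a)]
        replaced, report = realign_reads(reads, small_reference, small_index)
        assert report.attempted == 1 and report.accepted == 1
        (new,) = replaced.values()
        assert "100D" in str(new.cigar)
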