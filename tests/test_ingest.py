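"""Read QC, placement, SAM parsing and pileup construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastedit import dna
from plastedit.ingest import (
    Alignment,
    PileupSet,
    ReadRecord,
    build_pileup,
    place_reads,
    qc_filter,
    read_fastq,
    read_sam,
)


def _read(seq, mean_q, identifier="r1"):
    quals = np.full(len(seq), mean_q, dtype=np.uint8)
    return ReadRecord(identifier=identifier, sequence=seq, qualities=quals)


class TestQC:
    @pytest.mark.parametrize(
        "length,mean_q,passes",
        [
            (69, 35, False),  # too short despite high quality
            (100, 19, False),  # too low quality despite length
            (70, 20, True),  # both boundaries inclusive
            (100, 35, True),
        ],
    )
    def test_thresholds(self, length, mean_q, passes):
        kept, summary = qc_filter([_read("A" * length, mean_q)])
        assert (len(kept) == 1) is passes
        assert summary.total == 1

    def test_empty_input(self):
        kept, summary = qc_filter([])
        assert kept == [] and summary.total == 0 and summary.percent_passing == 0.0

    def test_fractional_mean_quality(self):
        r = ReadRecord("r", "A" * 80, np.array([19] * 40 + [21] * 40, dtype=np.uint8))
        kept, _ = qc_filter([r])
        assert len(kept) == 1  # mean exactly 20.0

    @given(
        min_q=st.integers(0, 40),
        min_len=st.integers(0, 150),
        stricter_q=st.integers(0, 5),
        stricter_len=st.integers(0, 30),
    )
    def test_monotonicity(self, min_q, min_len, stricter_q, stricter_len):
        rng = np.random.default_rng(min_q * 1000 + min_len)
        reads = [
            ReadRecord(
                f"r{i}",
                "A" * n,
                rng.integers(0, 41, n).astype(np.uint8),
            )
            for i, n in enumerate(rng.integers(10, 150, 30))
        ]
        loose, _ = qc_filter(reads, min_q, min_len)
        tight, _ = qc_filter(reads, min_q + stricter_q, min_len + stricter_len)
        assert len(tight) <= len(loose)


GENOME = "ACGTACGTAC" * 20  # 200 bp


def _tagged(seq, pos, strand, rep="f1", quals=None):
    q = quals if quals is not None else np.full(len(seq), 40, dtype=np.uint8)
    return ReadRecord(
        identifier=f"sim|rep={rep}|cond=fronds|pos={pos}|strand={strand}",
        sequence=seq,
        qualities=q,
        replicate_id=rep,
        condition="fronds",
    )


class TestPlacement:
    def test_perfect_forward_read(self):
        read = _tagged(GENOME[10:60], 11, "+")
        alns, summary = place_reads([read], GENOME)
        assert summary.placed == 1
        assert alns[0].segments == [(10, 0, 50)]
        assert alns[0].n_mismatches == 0

    def test_minus_read_is_transcript_oriented(self):
        read = _tagged(dna.revcomp(GENOME[10:60]), 11, "-")
        alns, _ = place_reads([read], GENOME)
        assert alns[0].n_mismatches == 0
        assert alns[0].strand == "-"

    def test_single_error_counted(self):
        seq = list(GENOME[10:60])
        seq[5] = "A" if seq[5] != "A" else "C"
        alns, _ = place_reads([_tagged("".join(seq), 11, "+")], GENOME)
        assert alns[0].n_mismatches == 1

    def test_origin_spanning_read_wraps(self):
        window = GENOME[190:] + GENOME[:40]
        alns, summary = place_reads([_tagged(window, 191, "+")], GENOME)
        assert summary.placed == 1
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        assert pileup.depth("f1", "+")[0] == 1  # position 1 covered via wrap

    def test_malformed_tag_is_unmapped(self, caplog):
        bad = ReadRecord("no_provenance_here", "ACGT" * 20, np.full(80, 40, dtype=np.uint8))
        alns, summary = place_reads([bad], GENOME)
        assert alns == [] and summary.unmapped_malformed == 1

    def test_divergent_read_is_unmapped(self):
        alns, summary = place_reads([_tagged("G" * 50, 11, "+")], GENOME)
        assert summary.unmapped_divergent == 1


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:plastome\tLN:200\n"


class TestReadSam:
    def _write(self, tmp_path, records):
        path = tmp_path / "in.sam"
        path.write_text(SAM_HEADER + "".join(records))
        return path

    def test_flag16_is_minus_strand(self, tmp_path):
        rec = f"r1\t16\tplastome\t11\t60\t50M\t*\t0\t0\t{GENOME[10:60]}\t{'I' * 50}\n"
        alns = read_sam(self._write(tmp_path, [rec]), replicate_id="f1", condition="fronds")
        assert len(alns) == 1 and alns[0].strand == "-"

    def test_unmapped_flag4_skipped(self, tmp_path):
        rec = "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        assert read_sam(self._write(tmp_path, [rec])) == []

    def test_soft_clips_excluded(self, tmp_path):
        seq = "T" * 10 + GENOME[10:70]
        rec = f"r1\t0\tplastome\t11\t60\t10S60M\t*\t0\t0\t{seq}\t{'I' * 70}\n"
        alns = read_sam(self._write(tmp_path, [rec]), replicate_id="f1")
        assert alns[0].segments == [(10, 10, 60)]
        pileup = build_pileup(alns, GENOME, min_base_quality=0, circular=False)
        assert pileup.total_bases() == 60

    def test_paired_end_rejected(self, tmp_path):
        rec = f"r1\t99\tplastome\t11\t60\t50M\t=\t100\t0\t{GENOME[10:60]}\t{'I' * 50}\n"
        with pytest.raises(ValueError, match="paired-end"):
            read_sam(self._write(tmp_path, [rec]))


class TestPileup:
    def test_forward_counts_fig4_pattern(self):
        """31 C + 2 T among 33 reads at one position, stored as read."""
        reads = []
        pos0 = 100  # GENOME[100] == 'A'; use a C position instead
        pos0 = GENOME.index("C", 50)
        for i in range(33):
            seq = list(GENOME[pos0 - 10 : pos0 + 40])
            if i < 2:
                seq[10] = "T"
            reads.append(_tagged("".join(seq), pos0 - 9, "+", rep="f1"))
        alns, _ = place_reads(reads, GENOME)
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        arr = pileup.counts["f1"]["+"]
        assert arr[dna.C, pos0] == 31
        assert arr[dna.T, pos0] == 2

    def test_minus_strand_stored_in_transcript_space(self):
        """5 G->A reads on the forward reference appear as T (edited C) counts."""
        pos0 = GENOME.index("G", 50)
        reads = []
        for i in range(12):
            window = list(GENOME[pos0 - 10 : pos0 + 40])
            if i < 5:
                window[10] = "A"  # genome-space A = transcript-space U
            reads.append(_tagged(dna.revcomp("".join(window)), pos0 - 9, "-", rep="f1"))
        alns, _ = place_reads(reads, GENOME)
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        arr = pileup.counts["f1"]["-"]
        assert arr[dna.T, pos0] == 5
        assert arr[dna.C, pos0] == 7

    def test_no_alignments_empty_pileup(self):
        pileup = build_pileup([], GENOME)
        assert pileup.total_bases() == 0
        assert list(pileup.columns()) == []

    def test_depth_conservation(self):
        rng = np.random.default_rng(7)
        reads = [
            _tagged(GENOME[s : s + 50], s + 1, "+")
            for s in rng.integers(0, 150, 40)
        ]
        alns, _ = place_reads(reads, GENOME)
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        assert pileup.total_bases() == sum(a.aligned_length for a in alns)

    def test_base_quality_filter_drops_bases(self):
        quals = np.full(50, 40, dtype=np.uint8)
        quals[:10] = 5
        reads = [_tagged(GENOME[10:60], 11, "+", quals=quals)]
        alns, _ = place_reads(reads, GENOME)
        assert build_pileup(alns, GENOME, min_base_quality=13).total_bases() == 40

    def test_complement_round_trip(self):
        reads = [_tagged(GENOME[10:60], 11, "+"), _tagged(dna.revcomp(GENOME[80:130]), 81, "-")]
        alns, _ = place_reads(reads, GENOME)
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        twice = pileup.complemented().complemented()
        for rep in pileup.counts:
            for s in "+-":
                assert (pileup.counts[rep][s] == twice.counts[rep][s]).all()

    def test_tsv_round_trip(self, tmp_path):
        reads = [_tagged(GENOME[10:60], 11, "+")]
        alns, _ = place_reads(reads, GENOME)
        pileup = build_pileup(alns, GENOME, min_base_quality=0)
        path = tmp_path / "pileup.tsv"
        pileup.to_tsv(path)
        back = PileupSet.from_tsv(path, len(GENOME))
        assert (back.counts["f1"]["+"] == pileup.counts["f1"]["+"]).all()
        assert back.condition_of == pileup.condition_of

    def test_noncircular_bounds_error(self):
        aln = Alignment(
            read_id="r", replicate_id="f1", condition="fronds", strand="+",
            seq_codes=dna.encode("A" * 50), quals=np.full(50, 40, dtype=np.uint8),
            segments=[(180, 0, 50)],
        )
        with pytest.raises(ValueError, match="non-circular"):
            build_pileup([aln], GENOME, circular=False)


def test_fastq_round_trip(tmp_path):
    from plastedit.simulate import write_fastq

    reads = [_tagged(GENOME[0:80], 1, "+"), _tagged(GENOME[5:90], 6, "+")]
    path = tmp_path / "reads.fastq"
    write_fastq(reads, path)
    back = read_fastq(path, replicate_id="f1", condition="fronds")
    assert [r.sequence for r in back] == [r.sequence for r in reads]
    assert all((a.qualities == b.qualities).all() for a, b in zip(back, reads))
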