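"""Read QC, alignment acquisition and strand-specific pileup construction.

Two alignment sources are supported: simulated reads, whose placement is
taken from the provenance tag in the FASTQ header and verified against the
genome, and single-end SAM files read through pysam.  Either way an
:class:`Alignment` records genome-forward-oriented bases, their qualities
and the aligned segments, and :func:`build_pileup` accumulates per-replicate,
per-strand base counts in *transcribed-strand space*: for a minus-strand
alignment the stored base is the base as read on the transcript, i.e. the
complement of the forward-genome base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import dna

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass
class ReadRecord:
    identifier: str
    sequence: str
    qualities: np.ndarray  # Phred scores, same length as sequence
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.identifier}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if len(self.qualities) else 0.0


def read_fastq(
    path: str | Path, replicate_id: str = "", condition: str = ""
) -> list[ReadRecord]:
    """Read a Phred+33 FASTQ file into ReadRecords."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            out.append(
                ReadRecord(
                    identifier=title,
                    sequence=seq,
                    qualities=scores,
                    replicate_id=replicate_id,
                    condition=condition,
                )
            )
    return out


# ------------------------------------------------------------------------- QC


@dataclass
class QCSummary:
    total: int
    passing: int

    @property
    def percent_passing(self) -> float:
        return 100.0 * self.passing / self.total if self.total else 0.0


def qc_filter(
    reads: Iterable[ReadRecord],
    min_mean_quality: float = 20.0,
    min_length: int = 70,
) -> tuple[list[ReadRecord], QCSummary]:
    """Keep reads with arithmetic-mean Phred >= threshold and length >= threshold.

    Both boundaries are inclusive.
    """
    total = 0
    passing = []
    for r in reads:
        total += 1
        if len(r.sequence) >= min_length and r.mean_quality >= min_mean_quality:
            passing.append(r)
    return passing, QCSummary(total=total, passing=len(passing))


# ------------------------------------------------------------------ alignments


@dataclass
class Alignment:
    """A placed single-end read, bases in genome-forward orientation.

    ``segments`` are (genome_start0, read_offset, length) triples covering
    the aligned (non-clipped) portion of the read; on a circular genome a
    segment may run past the origin and wraps modulo the genome length.
    """

    read_id: str
    replicate_id: str
    condition: str
    strand: str
    seq_codes: np.ndarray  # uint8, genome-forward orientation
    quals: np.ndarray  # aligned with seq_codes
    segments: list[tuple[int, int, int]]
    n_mismatches: int = 0

    @property
    def aligned_length(self) -> int:
        return sum(ln for _, _, ln in self.segments)


@dataclass
class PlacementSummary:
    total: int = 0
    placed: int = 0
    unmapped_malformed: int = 0
    unmapped_divergent: int = 0


def _parse_provenance(identifier: str) -> tuple[int, str]:
    tags = dict(
        kv.split("=", 1) for kv in identifier.split("|")[1:] if "=" in kv
    )
    pos = int(tags["pos"])
    strand = tags["strand"]
    if strand not in STRANDS or pos < 1:
        raise ValueError("bad provenance tag")
    return pos, strand


def place_reads(
    reads: Iterable[ReadRecord],
    genome: str,
    *,
    circular: bool = True,
    max_divergence: float = 0.10,
) -> tuple[list[Alignment], PlacementSummary]:
    """Place simulated reads using the provenance tag in their identifiers.

    Each read is verified against the genome at its tagged locus; reads
    whose mismatch fraction exceeds ``max_divergence`` (after allowing for
    editing and sequencing error) are counted as unmapped, as are reads
    with malformed tags.
    """
    genome_codes = dna.encode(genome)
    L = len(genome_codes)
    summary = PlacementSummary()
    alignments: list[Alignment] = []
    for r in reads:
        summary.total += 1
        try:
            pos1, strand = _parse_provenance(r.identifier)
        except (KeyError, ValueError, IndexError):
            logger.warning("malformed provenance tag on %s; treated as unmapped", r.identifier)
            summary.unmapped_malformed += 1
            continue
        start0 = pos1 - 1
        n = len(r.sequence)
        if not circular and start0 + n > L:
            raise ValueError(
                f"{r.identifier}: alignment past genome end in non-circular mode"
            )
        codes = dna.encode(r.sequence)
        quals = r.qualities
        if strand == "-":
            # FASTQ carries transcript orientation; flip to genome-forward
            codes = dna.revcomp_codes(codes)
            quals = quals[::-1]
        ref = dna.circular_slice(genome_codes, start0 % L, n)
        nm = int(np.count_nonzero(codes != ref))
        if nm > max(3, int(np.ceil(max_divergence * n))):
            summary.unmapped_divergent += 1
            continue
        alignments.append(
            Alignment(
                read_id=r.identifier,
                replicate_id=r.replicate_id,
                condition=r.condition,
                strand=strand,
                seq_codes=codes,
                quals=np.ascontiguousarray(quals),
                segments=[(start0 % L, 0, n)],
                n_mismatches=nm,
            )
        )
        summary.placed += 1
    return alignments, summary


_CIGAR_BOTH = {0, 7, 8}  # M, =, X
_CIGAR_QUERY = {1, 4}  # I, S
_CIGAR_REF = {2, 3}  # D, N


def read_sam(
    path: str | Path, replicate_id: str = "", condition: str = ""
) -> list[Alignment]:
    """Read single-end alignments from a headered SAM file via pysam.

    Unmapped records are skipped; paired-end flags are rejected; soft-clipped
    bases are excluded from the aligned segments (and hence from pileups).
    """
    import pysam

    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for i, rec in enumerate(sam, start=1):
            if rec.flag & 0x1:
                raise ValueError(f"{path}: record {i} is paired-end; only single-end SAM is supported")
            if rec.is_unmapped:
                continue
            if rec.query_sequence is None or rec.cigartuples is None:
                raise ValueError(f"{path}: record {i} lacks sequence or CIGAR")
            seq = dna.encode(rec.query_sequence)  # pysam stores genome-forward
            if rec.query_qualities is not None:
                quals = np.asarray(rec.query_qualities, dtype=np.uint8)
            else:
                quals = np.full(len(seq), 60, dtype=np.uint8)
            segments = []
            rpos, qpos = rec.reference_start, 0
            for op, ln in rec.cigartuples:
                if op in _CIGAR_BOTH:
                    segments.append((rpos, qpos, ln))
                    rpos += ln
                    qpos += ln
                elif op in _CIGAR_QUERY:
                    qpos += ln
                elif op in _CIGAR_REF:
                    rpos += ln
            alignments.append(
                Alignment(
                    read_id=rec.query_name or f"record{i}",
                    replicate_id=replicate_id,
                    condition=condition,
                    strand="-" if rec.is_reverse else "+",
                    seq_codes=seq,
                    quals=quals,
                    segments=segments,
                )
            )
    return alignments


# --------------------------------------------------------------------- pileups


@dataclass
class PileupColumn:
    """One (position, strand, replicate) pileup cell in transcribed-strand space."""

    genome_position: int  # 1-based
    strand: str
    replicate_id: str
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


class PileupSet:
    """Per-replicate, per-strand base counts over the genome.

    ``counts[rep][strand]`` is a (4, L) array; row order A, C, G, T; the
    stored base is the base as read on the transcript of that strand
    (minus-strand alignments are complemented on entry).
    """

    def __init__(self, genome_length: int):
        self.genome_length = genome_length
        self.counts: dict[str, dict[str, np.ndarray]] = {}
        self.condition_of: dict[str, str] = {}

    def _ensure(self, rep: str, condition: str) -> dict[str, np.ndarray]:
        if rep not in self.counts:
            self.counts[rep] = {
                s: np.zeros((4, self.genome_length), dtype=np.uint32) for s in STRANDS
            }
            self.condition_of[rep] = condition
        return self.counts[rep]

    @property
    def replicate_ids(self) -> list[str]:
        return sorted(self.counts)

    def depth(self, rep: str, strand: str) -> np.ndarray:
        return self.counts[rep][strand].sum(axis=0)

    def total_bases(self) -> int:
        return int(sum(arr.sum() for by in self.counts.values() for arr in by.values()))

    def complemented(self) -> "PileupSet":
        """Flip every count array into the opposite strand's base space."""
        out = PileupSet(self.genome_length)
        for rep, by in self.counts.items():
            out._ensure(rep, self.condition_of[rep])
            for s in STRANDS:
                out.counts[rep][s] = by[s][::-1].copy()  # A<->T, C<->G
        return out

    def columns(self) -> Iterator[PileupColumn]:
        """Non-empty pileup columns, for serialization."""
        for rep in self.replicate_ids:
            for s in STRANDS:
                arr = self.counts[rep][s]
                occupied = np.flatnonzero(arr.sum(axis=0))
                for p0 in occupied:
                    yield PileupColumn(
                        genome_position=int(p0) + 1,
                        strand=s,
                        replicate_id=rep,
                        base_counts={b: int(arr[i, p0]) for i, b in enumerate(dna.BASES)},
                    )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_position\tstrand\treplicate\tcondition\tA\tC\tG\tT\n")
            for col in self.columns():
                c = col.base_counts
                cond = self.condition_of.get(col.replicate_id, "")
                fh.write(
                    f"{col.genome_position}\t{col.strand}\t{col.replicate_id}\t{cond}"
                    f"\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "PileupSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"condition": str})
        pileup = cls(genome_length)
        for row in df.itertuples():
            by = pileup._ensure(str(row.replicate), str(row.condition))
            p0 = int(row.genome_position) - 1
            for i, b in enumerate(dna.BASES):
                by[row.strand][i, p0] = getattr(row, b)
        return pileup


def build_pileup(
    alignments: Iterable[Alignment],
    genome: str,
    *,
    min_base_quality: int = 13,
    circular: bool = True,
) -> PileupSet:
    """Accumulate strand-specific base counts from alignments.

    Bases below ``min_base_quality`` are excluded (the conventional pileup
    default in samtools-style callers).  Minus-strand bases are stored
    complemented so every count is in transcribed-strand space.
    """
    L = len(genome)
    pileup = PileupSet(L)
    for aln in alignments:
        by = pileup._ensure(aln.replicate_id, aln.condition)
        arr = by[aln.strand]
        for gstart0, roff, ln in aln.segments:
            if not circular and gstart0 + ln > L:
                raise ValueError(
                    f"{aln.read_id}: segment past genome end in non-circular mode"
                )
            pos = (gstart0 + np.arange(ln)) % L
            bases = aln.seq_codes[roff : roff + ln]
            quals = aln.quals[roff : roff + ln]
            keep = quals >= min_base_quality
            if aln.strand == "-":
                bases = (3 - bases).astype(np.uint8)
            np.add.at(arr, (bases[keep], pos[keep]), 1)
    return pileup
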