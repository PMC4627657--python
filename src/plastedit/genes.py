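"""Strand-aware gene models on a (circular) plastome and a strict GFF3 subset.

A :class:`GeneModel` is a set of ordered, non-overlapping exon intervals plus
CDS intervals nested inside them, all in 1-based inclusive genome
coordinates on the forward strand.  Transcription direction is given by
``strand``; coordinate arithmetic (spliced CDS offsets, region classes)
respects it.  Trans-spliced genes are not representable: exons must be
colinear on one strand.

The GFF3 reader/writer covers exactly the features this package emits
(gene, exon, CDS, five_prime_UTR, three_prime_UTR with ID/Parent
attributes); it is deliberately strict and fails loudly on anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dna

Interval = tuple[int, int]  # 1-based inclusive


def _length(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


@dataclass
class GeneModel:
    name: str
    strand: str  # '+' or '-'
    exons: list[Interval]  # ascending genome order, non-overlapping
    cds: list[Interval]  # subset of exon space, ascending genome order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        for ivs in (self.exons, self.cds):
            for (s, e) in ivs:
                if s > e:
                    raise ValueError(f"{self.name}: interval {s}-{e} reversed")
            for (a, b) in zip(ivs, ivs[1:]):
                if b[0] <= a[1]:
                    raise ValueError(f"{self.name}: intervals overlap or unsorted")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.name}: spliced CDS length {self.cds_length} not divisible by 3"
            )

    # ------------------------------------------------------------------ spans
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(_length(iv) for iv in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(_length(iv) for iv in self.exons)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    # ------------------------------------------------------------- region class
    def region_of(self, position: int) -> str | None:
        """Classify a genome position: 'CDS', 'intron', "5'UTR", "3'UTR" or None."""
        if not self.contains(position):
            return None
        for s, e in self.cds:
            if s <= position <= e:
                return "CDS"
        in_exon = any(s <= position <= e for s, e in self.exons)
        if not in_exon:
            return "intron"
        # exonic but non-coding: side relative to the CDS decides which UTR
        if not self.cds:
            return "5'UTR"
        before_cds = position < self.cds[0][0]
        if self.strand == "+":
            return "5'UTR" if before_cds else "3'UTR"
        return "3'UTR" if before_cds else "5'UTR"

    # -------------------------------------------------------- spliced coordinates
    def cds_offset(self, position: int) -> int:
        """1-based offset of a genomic position within the spliced CDS,
        counted in transcription direction."""
        if self.region_of(position) != "CDS":
            raise ValueError(
                f"position {position} is not in the CDS of {self.name}"
            )
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if position > e:
                    off += e - s + 1
                else:
                    return off + position - s + 1
        else:
            off = 0
            for s, e in reversed(self.cds):
                if position < s:
                    off += e - s + 1
                else:
                    return off + e - position + 1
        raise AssertionError("unreachable")

    def cds_genome_position(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        if not 1 <= offset <= self.cds_length:
            raise ValueError(f"CDS offset {offset} outside 1..{self.cds_length}")
        remaining = offset
        intervals = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in intervals:
            n = e - s + 1
            if remaining <= n:
                return s + remaining - 1 if self.strand == "+" else e - remaining + 1
            remaining -= n
        raise AssertionError("unreachable")

    def spliced_cds_codes(self, genome_codes: np.ndarray) -> np.ndarray:
        """The spliced CDS as base codes, 5'->3' on the transcribed strand."""
        parts = [genome_codes[s - 1 : e] for s, e in self.cds]
        joined = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        if self.strand == "-":
            joined = dna.revcomp_codes(joined)
        return joined


def transcribed_base(genome_codes: np.ndarray, position: int, strand: str) -> int:
    """Base code at a 1-based position as read on the given transcript strand."""
    b = int(genome_codes[position - 1])
    return b if strand == "+" else 3 - b


# ---------------------------------------------------------------------- GFF3 IO

_GFF_COLS = 9


def write_gff3(genes: list[GeneModel], path: str | Path, seqid: str = "plastome") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: g.start):
        gid = f"gene:{g.name}"
        attrs = f"ID={gid};Name={g.name}"
        lines.append(
            f"{seqid}\tplastedit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for s, e in g.exons:
            lines.append(
                f"{seqid}\tplastedit\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={gid}"
            )
        phase_consumed = 0
        cds_ivs = g.cds if g.strand == "+" else list(reversed(g.cds))
        phased: dict[Interval, int] = {}
        for iv in cds_ivs:
            phased[iv] = (3 - phase_consumed % 3) % 3
            phase_consumed += _length(iv)
        for s, e in g.cds:
            lines.append(
                f"{seqid}\tplastedit\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phased[(s, e)]}\tParent={gid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != _GFF_COLS:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
        _, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        iv = (int(start), int(end))
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = {
                "name": attr.get("Name", gid.removeprefix("gene:")),
                "strand": strand,
                "exons": [],
                "cds": [],
            }
            order.append(gid)
        elif ftype in ("exon", "CDS"):
            parent = attr["Parent"]
            if parent not in genes:
                raise ValueError(f"GFF3 line {lineno}: Parent {parent} unknown")
            genes[parent]["exons" if ftype == "exon" else "cds"].append(iv)
        elif ftype in ("five_prime_UTR", "three_prime_UTR"):
            continue  # derivable from exon/CDS
        else:
            raise ValueError(f"GFF3 line {lineno}: unsupported feature type {ftype!r}")
    out = []
    for gid in order:
        rec = genes[gid]
        out.append(
            GeneModel(
                name=rec["name"],
                strand=rec["strand"],
                exons=sorted(rec["exons"]),
                cds=sorted(rec["cds"]),
            )
        )
    return out


def genes_covering(genes: list[GeneModel], position: int, strand: str | None = None):
    """All gene models whose span contains the position (optionally strand-matched)."""
    return [
        g
        for g in genes
        if g.contains(position) and (strand is None or g.strand == strand)
    ]
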