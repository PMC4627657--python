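"""Codon-level annotation of editing sites on plastid gene models.

Coordinates follow the conventions of published chloroplast editing
tables: gene position is the 1-based offset within the spliced CDS in
transcription direction, codon offset is ``((gene_position - 1) mod 3) + 1``,
and codons are printed as lowercase RNA with the edited base uppercase
(``cCa`` -> ``cUa``).  Translation uses the plastid/bacterial genetic code
(NCBI table 11).  An ACG codon at codon 1 whose editing yields AUG is a
start gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from . import dna
from .genes import GeneModel, genes_covering

PLASTID_TABLE = 11


class AmbiguousLocationError(ValueError):
    """A position lies inside two same-strand gene models."""


def locate_site(
    position: int, strand: str, genes: Sequence[GeneModel]
) -> tuple[str, str | None]:
    """Region class and gene for a genomic position on a transcript strand.

    Returns one of ('CDS'|'intron'|"5'UTR"|"3'UTR", gene_name) or
    ('intergenic', None).
    """
    hits = genes_covering(list(genes), position, strand)
    if len(hits) > 1:
        names = ", ".join(g.name for g in hits)
        raise AmbiguousLocationError(
            f"position {position} ({strand}) lies in multiple genes: {names}"
        )
    if not hits:
        return "intergenic", None
    gene = hits[0]
    region = gene.region_of(position)
    assert region is not None
    return region, gene.name


def cds_position(position: int, gene: GeneModel) -> int:
    """1-based offset of a genomic position in the spliced CDS (introns excluded),
    counted from the gene's own 5' end."""
    return gene.cds_offset(position)


def translate_codon(codon: str) -> str:
    """Single-letter amino acid of an RNA/DNA codon under the plastid code."""
    return str(Seq(codon.upper().replace("U", "T")).translate(table=PLASTID_TABLE))


def format_codon(codon: str, offset: int) -> str:
    """Lowercase-RNA codon string with the base at ``offset`` (1..3) uppercase."""
    rna = codon.lower().replace("t", "u")
    return rna[: offset - 1] + rna[offset - 1].upper() + rna[offset:]


@dataclass
class SiteAnnotation:
    region_class: str
    gene_name: str | None = None
    gene_position: int | None = None
    codon_number: int | None = None
    codon_offset: int | None = None  # 1, 2 or 3
    ref_codon: str | None = None  # e.g. "uCa"
    edited_codon: str | None = None  # e.g. "uUa"
    aa_change: str | None = None  # "X>Y"
    effect: str | None = None  # missense | silent | start_gain


def codon_effect(gene_position: int, ref_codon: str) -> SiteAnnotation:
    """Annotate the codon-level consequence of editing the C at
    ``gene_position`` within a codon whose unedited sequence is ``ref_codon``."""
    offset = (gene_position - 1) % 3 + 1
    codon_number = (gene_position - 1) // 3 + 1
    rna = ref_codon.lower().replace("t", "u")
    if len(rna) != 3:
        raise ValueError(f"ref codon {ref_codon!r} is not a triplet")
    if rna[offset - 1] != "c":
        raise ValueError(
            f"codon {ref_codon!r} has {rna[offset - 1].upper()!r}, not C, at offset {offset}"
        )
    edited = rna[: offset - 1] + "u" + rna[offset:]
    aa_ref = translate_codon(rna)
    aa_edit = translate_codon(edited)
    if codon_number == 1 and rna == "acg" and edited == "aug":
        effect = "start_gain"
    elif aa_ref == aa_edit:
        effect = "silent"
    else:
        effect = "missense"
    return SiteAnnotation(
        region_class="CDS",
        gene_position=gene_position,
        codon_number=codon_number,
        codon_offset=offset,
        ref_codon=format_codon(rna, offset),
        edited_codon=format_codon(edited, offset),
        aa_change=f"{aa_ref}>{aa_edit}",
        effect=effect,
    )


def annotate_site(
    position: int,
    strand: str,
    genes: Sequence[GeneModel],
    genome: str,
) -> SiteAnnotation:
    """Full annotation of a genomic editing site against the gene models."""
    region, gene_name = locate_site(position, strand, genes)
    if region != "CDS":
        return SiteAnnotation(region_class=region, gene_name=gene_name)
    gene = next(g for g in genes if g.name == gene_name)
    gp = cds_position(position, gene)
    codon_number = (gp - 1) // 3 + 1
    cds_codes = gene.spliced_cds_codes(dna.encode(genome))
    codon = dna.decode(cds_codes[3 * (codon_number - 1) : 3 * codon_number])
    ann = codon_effect(gp, codon)
    ann.gene_name = gene_name
    return ann


# --------------------------------------------------------- fixture consistency


@dataclass
class FixtureMismatch:
    site: str
    field: str
    expected: str
    recomputed: str


@dataclass
class FixtureConsistencyReport:
    n_checked: int
    n_matched: int
    mismatches: list[FixtureMismatch]


def _is_silent_change(aa_change: str) -> bool:
    parts = aa_change.split(">")
    return len(parts) == 2 and parts[0] == parts[1]


def annotate_fixture(fixture: pd.DataFrame) -> FixtureConsistencyReport:
    """Re-derive codon offset and amino-acid change for every coding row of
    the packaged site table and compare with the printed columns.

    The codon offset must equal the uppercase position of the printed codon
    string.  Amino-acid changes are compared literally for missense and
    start-gain rows; synonymous rows are checked for synonymy of the
    recomputed change (the residue letter of a silent edit is redundant, and
    one printed silent row carries a residue letter inconsistent with its
    own codon).
    """
    mismatches: list[FixtureMismatch] = []
    coding = fixture[fixture["region"] == "CDS"]
    for row in coding.itertuples():
        gp = int(row.gene_position)
        offset = (gp - 1) % 3 + 1
        upper_at = next(
            (i + 1 for i, ch in enumerate(row.codon) if ch.isupper()), None
        )
        row_ok = True
        if upper_at != offset:
            mismatches.append(
                FixtureMismatch(row.site, "codon_offset", str(upper_at), str(offset))
            )
            row_ok = False
        else:
            try:
                ann = codon_effect(gp, row.codon)
            except ValueError as exc:
                mismatches.append(FixtureMismatch(row.site, "codon", row.codon, str(exc)))
                row_ok = False
            else:
                printed = row.aa_change
                if _is_silent_change(printed):
                    ok = ann.effect == "silent"
                else:
                    ok = ann.aa_change == printed
                if not ok:
                    mismatches.append(
                        FixtureMismatch(row.site, "aa_change", printed, ann.aa_change)
                    )
                    row_ok = False
        _ = row_ok
    n = len(coding)
    return FixtureConsistencyReport(
        n_checked=n,
        n_matched=n - len({m.site for m in mismatches}),
        mismatches=mismatches,
    )


def annotate_calls(calls, genes: Sequence[GeneModel], genome: str) -> pd.DataFrame:
    """Annotate a list of :class:`~plastedit.calling.EditingSiteCall` into the
    tabular form the reports and summaries consume."""
    from .calling import round_percent

    rows = []
    for c in calls:
        ann = annotate_site(c.genome_position, c.strand, genes, genome)
        label = ann.gene_name or "intergenic"
        rows.append(
            {
                "site": f"{label}@{c.genome_position}",
                "gene": ann.gene_name,
                "region": ann.region_class,
                "genome_position": c.genome_position,
                "strand": c.strand,
                "gene_position": ann.gene_position,
                "codon": ann.ref_codon or "-",
                "edited_codon": ann.edited_codon or "-",
                "aa_change": ann.aa_change or "-",
                "effect": ann.effect or "-",
                "fronds_pct": (
                    round_percent(c.efficiency_fronds)
                    if c.efficiency_fronds is not None
                    else None
                ),
                "turions_pct": (
                    round_percent(c.efficiency_turions)
                    if c.efficiency_turions is not None
                    else None
                ),
                "replicate_support": c.replicate_support,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "site", "gene", "region", "genome_position", "strand", "gene_position",
            "codon", "edited_codon", "aa_change", "effect",
            "fronds_pct", "turions_pct", "replicate_support",
        ],
    )
    if len(df):
        df = df.sort_values("genome_position").reset_index(drop=True)
    return df
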