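"""Synthetic plastome and strand-specific RNA-seq read simulation.

The generator emulates the statistical structure of deep total-RNA
sequencing of a plastid: a circular genome carrying non-overlapping genes
on both strands (a configurable fraction with one intron), per-condition
biological replicates, deep uniform coverage on both strands (plastid
transcription is pervasive and polycistronic, and total-RNA libraries
retain unspliced precursors, which is what makes intron and intergenic
editing observable), and partial C-to-U editing drawn per read per site as
a Bernoulli trial at the site's per-condition efficiency.

Sequencing errors follow Phred semantics: every base receives a quality
from a two-component profile (Q40 background, a thin Q7 tail) and is
miscalled with probability ``10**(-Q/10)``, with the mixture weight solved
so the mean per-base substitution rate equals ``error_rate`` exactly.
Substitutions are uniform over the three alternative bases; there are no
indels.  A configurable fraction of reads is emitted deliberately failing
the downstream QC rule (mean quality < 20 or length < 70).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from . import dna
from .genes import GeneModel, genes_covering
from .ingest import ReadRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
CONDITIONS = ("fronds", "turions")

Q_HIGH = 40  # background base quality; miscall probability 1e-4
Q_LOW = 7  # error-prone tail;        miscall probability ~0.1995
Q_REJECT = 10  # whole-read quality for deliberately low-quality reads
_P_HIGH = 10.0 ** (-Q_HIGH / 10.0)
_P_LOW = 10.0 ** (-Q_LOW / 10.0)


class ConfigurationError(ValueError):
    """The simulation configuration is internally infeasible."""


@dataclass
class SimulationConfig:
    genome_length: int = 15_000
    gene_count: int = 20
    intron_fraction: float = 0.15
    n_replicates_per_condition: int = 4
    mean_coverage: float = 200.0
    read_length: int = 100
    error_rate: float = 0.001
    low_quality_read_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ConfigurationError("genome_length must be >= 1000")
        if not 0.0 <= self.error_rate < 0.05:
            raise ConfigurationError("error_rate must be in [0, 0.05)")
        if self.n_replicates_per_condition < 1:
            raise ConfigurationError("need at least one replicate per condition")
        if self.read_length < 20:
            raise ConfigurationError("read_length must be >= 20")
        if not 0.0 <= self.low_quality_read_fraction < 1.0:
            raise ConfigurationError("low_quality_read_fraction must be in [0, 1)")
        if not 0.0 <= self.intron_fraction <= 1.0:
            raise ConfigurationError("intron_fraction must be in [0, 1]")
        if self.gene_count < 0:
            raise ConfigurationError("gene_count must be >= 0")


@dataclass(frozen=True)
class GroundTruthSite:
    """An implanted editing site with its true per-condition efficiencies."""

    genome_position: int  # 1-based, forward strand
    transcribed_strand: str  # '+' or '-'
    efficiency_fronds: float  # fraction in [0, 1]
    efficiency_turions: float
    region: str = "CDS"
    gene: str | None = None

    def efficiency(self, condition: str) -> float:
        return {
            "fronds": self.efficiency_fronds,
            "turions": self.efficiency_turions,
        }[condition]


# --------------------------------------------------------------------- plastome


def _random_cds_codes(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """ATG + (n_codons) non-stop codons + one stop codon, as base codes."""
    non_stop = [
        (a, b, c)
        for a in range(4)
        for b in range(4)
        for c in range(4)
        if dna.decode(np.array([a, b, c], dtype=np.uint8)) not in STOP_CODONS
    ]
    non_stop_arr = np.array(non_stop, dtype=np.uint8)
    body = non_stop_arr[rng.integers(0, len(non_stop_arr), n_codons)].ravel()
    start = dna.encode("ATG")
    stop = dna.encode(STOP_CODONS[rng.integers(0, 3)])
    return np.concatenate([start, body, stop])


def build_synthetic_plastome(config: SimulationConfig) -> tuple[str, list[GeneModel]]:
    """Generate a circular genome and a compatible gene-model set.

    Genes carry short UTRs, optionally one intron inside the CDS, sit on
    either strand, never overlap and never span the origin.  Every spliced
    CDS starts with ATG, ends with a stop and is free of internal stops by
    construction.
    """
    rng = np.random.default_rng([config.seed, 101])
    L = config.genome_length
    genome = rng.integers(0, 4, L).astype(np.uint8)

    utr = 30
    min_gap = 20
    plans = []
    for i in range(config.gene_count):
        n_codons = int(rng.integers(100, 181))
        has_intron = rng.random() < config.intron_fraction
        intron_len = int(rng.integers(120, 301)) if has_intron else 0
        cds_len = 3 * (n_codons + 2)
        span = utr + cds_len + intron_len + utr
        plans.append((n_codons, cds_len, intron_len, span))

    total = sum(p[3] for p in plans) + min_gap * (config.gene_count + 1)
    if total > L:
        raise ConfigurationError(
            f"gene_count={config.gene_count} needs {total} bp but genome_length={L}"
        )

    # distribute the slack as random intergenic gaps
    slack = L - total
    if config.gene_count:
        cuts = np.sort(rng.integers(0, slack + 1, config.gene_count))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + min_gap
    else:
        gaps = np.array([L], dtype=int)

    genes: list[GeneModel] = []
    cursor = int(gaps[0])  # 0-based start of next gene span
    for i, (n_codons, cds_len, intron_len, span) in enumerate(plans):
        strand = "+" if rng.random() < 0.5 else "-"
        cds_codes = _random_cds_codes(rng, n_codons)
        assert len(cds_codes) == cds_len

        g_start = cursor + 1  # 1-based
        g_end = cursor + span
        cds_lo = g_start + utr
        cds_hi = cds_lo + cds_len + intron_len - 1
        if intron_len:
            # intron inserted at a codon boundary, never at the extreme ends
            k = int(rng.integers(3, cds_len - 3))
            k -= k % 3
            intron_lo = cds_lo + k
            intron_hi = intron_lo + intron_len - 1
            exons = [(g_start, intron_lo - 1), (intron_hi + 1, g_end)]
            cds_ivs = [(cds_lo, intron_lo - 1), (intron_hi + 1, cds_hi)]
        else:
            exons = [(g_start, g_end)]
            cds_ivs = [(cds_lo, cds_hi)]

        # write the CDS into the forward genome (reverse-complemented for '-')
        oriented = cds_codes if strand == "+" else dna.revcomp_codes(cds_codes)
        written = 0
        ivs = cds_ivs if strand == "+" else cds_ivs  # genome order either way
        for s, e in ivs:
            n = e - s + 1
            genome[s - 1 : e] = oriented[written : written + n]
            written += n

        genes.append(GeneModel(name=f"g{i + 1:03d}", strand=strand, exons=exons, cds=cds_ivs))
        cursor = g_end + int(gaps[i + 1])

    return dna.decode(genome), genes


# ----------------------------------------------------------------- ground truth


def _eligible_positions(
    genome_codes: np.ndarray, genes: list[GeneModel], region: str
) -> list[tuple[int, str]]:
    """(position, transcribed strand) pairs with C on the transcript, by region."""
    out = []
    L = len(genome_codes)
    if region == "intergenic":
        covered = np.zeros(L, dtype=bool)
        for g in genes:
            covered[g.start - 1 : g.end] = True
        for p0 in np.flatnonzero(~covered):
            pos = int(p0) + 1
            if genome_codes[p0] == dna.C:
                out.append((pos, "+"))
            elif genome_codes[p0] == dna.G:
                out.append((pos, "-"))
        return out
    for g in genes:
        for pos in range(g.start, g.end + 1):
            if g.region_of(pos) != region:
                continue
            from .genes import transcribed_base

            if transcribed_base(genome_codes, pos, g.strand) == dna.C:
                out.append((pos, g.strand))
    return out


def implant_editing_sites(
    genome: str,
    genes: list[GeneModel],
    n_sites: int,
    efficiencies: Sequence[tuple[float, float]] | None = None,
    *,
    noncoding: dict[str, int] | None = None,
    efficiency_range: tuple[float, float] = (0.06, 1.0),
    seed: int = 0,
) -> list[GroundTruthSite]:
    """Choose editing sites (C on the transcribed strand) and assign true
    per-condition efficiencies.

    ``efficiencies`` may fix (fronds, turions) fractions per site; otherwise
    both are drawn uniformly from ``efficiency_range`` (the span observed in
    chloroplast editomes).  ``noncoding`` requests a subset of sites in
    non-CDS regions, e.g. ``{"intron": 2, "5'UTR": 1, "intergenic": 5}``.
    """
    rng = np.random.default_rng([seed, 202])
    if n_sites == 0:
        return []
    genome_codes = dna.encode(genome)
    noncoding = dict(noncoding or {})
    n_cds = n_sites - sum(noncoding.values())
    if n_cds < 0:
        raise ConfigurationError("noncoding site counts exceed n_sites")

    wanted = [("CDS", n_cds)] + list(noncoding.items())
    chosen: list[tuple[int, str, str]] = []
    used: set[int] = set()
    for region, k in wanted:
        pool = [ps for ps in _eligible_positions(genome_codes, genes, region) if ps[0] not in used]
        if len(pool) < k:
            raise ConfigurationError(
                f"only {len(pool)} eligible C positions in {region}, need {k} "
                f"(short by {k - len(pool)})"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        for j in idx:
            pos, strand = pool[j]
            used.add(pos)
            chosen.append((pos, strand, region))

    if efficiencies is not None:
        if len(efficiencies) != n_sites:
            raise ConfigurationError("efficiencies length must equal n_sites")
        effs = [tuple(e) for e in efficiencies]
    else:
        lo, hi = efficiency_range
        effs = [(float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))) for _ in range(n_sites)]

    sites = []
    for (pos, strand, region), (ef, et) in zip(chosen, effs):
        if not (0.0 <= ef <= 1.0 and 0.0 <= et <= 1.0):
            raise ConfigurationError("efficiencies must lie in [0, 1]")
        covering = genes_covering(genes, pos, strand)
        sites.append(
            GroundTruthSite(
                genome_position=pos,
                transcribed_strand=strand,
                efficiency_fronds=ef,
                efficiency_turions=et,
                region=region,
                gene=covering[0].name if covering else None,
            )
        )
    sites.sort(key=lambda s: s.genome_position)
    return sites


# ----------------------------------------------------------------------- reads


def _quality_mixture_weight(error_rate: float) -> float:
    """Weight of the Q7 component so the mean miscall rate equals error_rate."""
    if error_rate <= _P_HIGH:
        return 0.0
    return (error_rate - _P_HIGH) / (_P_LOW - _P_HIGH)


def simulate_reads(
    genome: str,
    truth: Sequence[GroundTruthSite],
    condition: str,
    replicate_id: str,
    config: SimulationConfig,
    *,
    replicate_index: int = 0,
) -> list[ReadRecord]:
    """Simulate one replicate's single-end reads for one condition.

    Reads are contiguous genomic windows from both strands (circular
    coordinates); minus-strand reads are emitted in transcript orientation
    (reverse complement of the forward genome).  Each FASTQ identifier
    carries its provenance: ``sim|rep=..|cond=..|pos=<1-based start>|strand=..``.
    Expected per-position depth on each strand is ``mean_coverage``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    cond_code = CONDITIONS.index(condition)
    rng = np.random.default_rng([config.seed, 303, cond_code, replicate_index])
    genome_codes = dna.encode(genome)
    L = len(genome_codes)
    rl = min(config.read_length, L)
    n_reads = int(round(L * config.mean_coverage / rl))
    w_low = _quality_mixture_weight(config.error_rate)

    reads: list[ReadRecord] = []
    for strand in "+-":
        starts0 = rng.integers(0, L, n_reads)
        cols = (starts0[:, None] + np.arange(rl)) % L
        matrix = genome_codes[cols]  # genome forward orientation

        # C->U editing on the transcribed strand: per covered read, Bernoulli
        for site in truth:
            if site.transcribed_strand != strand:
                continue
            eff = site.efficiency(condition)
            if eff == 0.0:
                continue
            offset = (site.genome_position - 1 - starts0) % L
            covered = np.flatnonzero(offset < rl)
            if covered.size == 0:
                continue
            edited = covered[rng.random(covered.size) < eff]
            # transcript C->U is genome-space T on '+', A on '-'
            matrix[edited, offset[edited]] = dna.T if strand == "+" else dna.A

        # Phred-calibrated sequencing errors
        quals = np.full((n_reads, rl), Q_HIGH, dtype=np.uint8)
        if w_low > 0.0:
            quals[rng.random((n_reads, rl)) < w_low] = Q_LOW
        if config.error_rate > 0.0:
            p_err = np.where(quals == Q_HIGH, _P_HIGH, _P_LOW)
            err = rng.random((n_reads, rl)) < p_err
            n_err = int(err.sum())
            if n_err:
                matrix[err] = (matrix[err] + rng.integers(1, 4, n_err)) % 4

        # deliberately QC-failing reads: half low quality, half short
        fail = np.flatnonzero(rng.random(n_reads) < config.low_quality_read_fraction)
        fail_short = fail[rng.random(fail.size) < 0.5]
        fail_lowq = np.setdiff1d(fail, fail_short)
        quals[fail_lowq] = Q_REJECT
        short_len = {int(i): int(rng.integers(rl // 3, 70)) for i in fail_short}

        for i in range(n_reads):
            seq_codes = matrix[i]
            q = quals[i]
            if i in short_len:
                ln = min(short_len[i], rl)
                seq_codes = seq_codes[:ln]
                q = q[:ln]
            if strand == "-":
                seq = dna.decode(dna.revcomp_codes(seq_codes))
                q = q[::-1]
            else:
                seq = dna.decode(seq_codes)
            reads.append(
                ReadRecord(
                    identifier=(
                        f"sim|rep={replicate_id}|cond={condition}"
                        f"|pos={int(starts0[i]) + 1}|strand={strand}|n={i}"
                    ),
                    sequence=seq,
                    qualities=np.ascontiguousarray(q),
                    replicate_id=replicate_id,
                    condition=condition,
                )
            )
    return reads


def simulate_experiment(
    genome: str,
    truth: Sequence[GroundTruthSite],
    config: SimulationConfig,
) -> dict[str, list[ReadRecord]]:
    """All replicates of both conditions; keys like ``fronds_1`` .. ``turions_4``."""
    out: dict[str, list[ReadRecord]] = {}
    for condition in CONDITIONS:
        for r in range(config.n_replicates_per_condition):
            rep_id = f"{condition}_{r + 1}"
            out[rep_id] = simulate_reads(
                genome, truth, condition, rep_id, config, replicate_index=r
            )
    return out


# -------------------------------------------------------------------- file IO


def write_fasta(genome: str, path: str | Path, name: str = "plastome") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(genome), id=name, description="")], str(path), "fasta")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.qualities + 33).tobytes().decode("ascii")
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{qual}\n")


def write_truth(truth: Sequence[GroundTruthSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_position\ttranscribed_strand\tefficiency_fronds\t"
                 "efficiency_turions\tregion\tgene\n")
        for s in truth:
            fh.write(
                f"{s.genome_position}\t{s.transcribed_strand}\t{s.efficiency_fronds:.6g}"
                f"\t{s.efficiency_turions:.6g}\t{s.region}\t{s.gene or '.'}\n"
            )


def read_truth(path: str | Path) -> list[GroundTruthSite]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthSite(
            genome_position=int(r.genome_position),
            transcribed_strand=str(r.transcribed_strand),
            efficiency_fronds=float(r.efficiency_fronds),
            efficiency_turions=float(r.efficiency_turions),
            region=str(r.region),
            gene=None if r.gene == "." else str(r.gene),
        )
        for r in df.itertuples()
    ]
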