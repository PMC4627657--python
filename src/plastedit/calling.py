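"""C-to-U editing-site calling from replicate pileups.

The filter cascade mirrors how organellar editing sites are called from
deep strand-specific RNA-seq: a position is a per-replicate candidate when
the transcribed-strand reference base is C, replicate depth reaches
``min_coverage`` (default 10) and at least ``min_edited_reads`` (default 2)
reads carry T; a site is emitted only when that condition holds in at least
``min_replicates`` replicates (default 2, counted across both conditions).
Editing efficiency is edited reads divided by total mapped reads, pooled
over each condition's replicates.

Mismatches other than C-to-T on the transcribed strand are never editing
calls; they are collected separately as non-canonical variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import dna
from .genes import GeneModel
from .ingest import PileupSet, STRANDS

logger = logging.getLogger(__name__)


def compute_efficiency(edited: int, total: int) -> float:
    """Editing efficiency in percent: 100 * edited / total."""
    if total <= 0:
        raise ValueError("editing efficiency is undefined for zero total reads")
    if edited > total:
        raise ValueError(f"edited reads ({edited}) exceed total reads ({total})")
    return 100.0 * edited / total


def round_percent(value: float) -> int:
    """Half-up rounding to integer percent, as printed in editing tables."""
    return int(math.floor(value + 0.5))


@dataclass
class CandidateSite:
    genome_position: int  # 1-based
    strand: str
    per_replicate: dict[str, tuple[int, int]]  # rep -> (edited, total)
    candidate_replicates: list[str]  # reps where the per-replicate filter held
    condition_of: dict[str, str]

    def pooled(self, condition: str | None = None) -> tuple[int, int]:
        """(edited, total) summed over replicates, optionally one condition's."""
        edited = total = 0
        for rep, (e, t) in self.per_replicate.items():
            if condition is None or self.condition_of[rep] == condition:
                edited += e
                total += t
        return edited, total


@dataclass
class EditingSiteCall:
    genome_position: int
    strand: str
    per_replicate: dict[str, tuple[int, int]]
    condition_of: dict[str, str]
    replicate_support: int
    efficiency_fronds: float | None  # percent, None if the condition has no reads
    efficiency_turions: float | None

    def pooled(self, condition: str | None = None) -> tuple[int, int]:
        edited = total = 0
        for rep, (e, t) in self.per_replicate.items():
            if condition is None or self.condition_of[rep] == condition:
                edited += e
                total += t
        return edited, total


@dataclass
class NonCanonicalVariant:
    genome_position: int
    strand: str
    ref_base: str
    alt_base: str
    n_replicates: int


@dataclass
class CallResult:
    candidates: list[CandidateSite]
    non_canonical: list[NonCanonicalVariant]


def _strand_allowed(genome_length: int, genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    """Which transcript strand(s) are considered at each position.

    Genic positions are examined on the annotated transcript strand only;
    intergenic positions on both strands.
    """
    genic = np.zeros(genome_length, dtype=bool)
    on = {s: np.zeros(genome_length, dtype=bool) for s in STRANDS}
    for g in genes:
        genic[g.start - 1 : g.end] = True
        on[g.strand][g.start - 1 : g.end] = True
    allowed = {s: on[s] | ~genic for s in STRANDS}
    return allowed


def call_candidates(
    pileups: PileupSet,
    genome: str,
    genes: Sequence[GeneModel] = (),
    min_coverage: int = 10,
    min_edited_reads: int = 2,
) -> CallResult:
    """Scan the pileups for per-replicate C-to-T candidates.

    Returns every (position, strand) with at least one candidate replicate,
    carrying (edited, total) counts for *all* replicates so downstream
    pooling is exact, plus the non-canonical variant report.
    """
    genome_codes = dna.encode(genome)
    L = len(genome_codes)
    if pileups.genome_length != L:
        raise ValueError("pileup and genome lengths differ")
    allowed = _strand_allowed(L, list(genes))
    reps = pileups.replicate_ids

    candidates: list[CandidateSite] = []
    non_canonical: dict[tuple[int, str, str, str], int] = {}
    for strand in STRANDS:
        # transcribed-strand reference base per forward position
        ref_t = genome_codes if strand == "+" else (3 - genome_codes).astype(np.uint8)
        ref_is_c = (ref_t == dna.C) & allowed[strand]

        depth = np.stack([pileups.depth(rep, strand) for rep in reps])
        tcount = np.stack([pileups.counts[rep][strand][dna.T] for rep in reps])
        cand = ref_is_c[None, :] & (depth >= min_coverage) & (tcount >= min_edited_reads)
        hit_positions = np.flatnonzero(cand.any(axis=0))
        for p0 in hit_positions:
            pos = int(p0) + 1
            per_rep = {}
            cand_reps = []
            for i, rep in enumerate(reps):
                per_rep[rep] = (int(tcount[i, p0]), int(depth[i, p0]))
                if cand[i, p0]:
                    cand_reps.append(rep)
            candidates.append(
                CandidateSite(
                    genome_position=pos,
                    strand=strand,
                    per_replicate=per_rep,
                    candidate_replicates=cand_reps,
                    condition_of=dict(pileups.condition_of),
                )
            )

        # non-canonical variants: any alt != transcribed ref other than C->T
        for i, rep in enumerate(reps):
            arr = pileups.counts[rep][strand]
            for alt in range(4):
                altcnt = arr[alt]
                mask = (
                    allowed[strand]
                    & (ref_t != alt)
                    & (altcnt >= min_edited_reads)
                    & (depth[i] >= min_coverage)
                    & ~(ref_is_c & (alt == dna.T))
                )
                for p0 in np.flatnonzero(mask):
                    key = (int(p0) + 1, strand, dna.BASES[ref_t[p0]], dna.BASES[alt])
                    non_canonical[key] = non_canonical.get(key, 0) + 1

    nc = [
        NonCanonicalVariant(pos, strand, ref, alt, n)
        for (pos, strand, ref, alt), n in sorted(non_canonical.items())
    ]
    candidates.sort(key=lambda c: (c.genome_position, c.strand))
    return CallResult(candidates=candidates, non_canonical=nc)


def apply_replicate_filter(
    candidates: Iterable[CandidateSite],
    min_replicates: int = 2,
    within_condition: bool = False,
) -> list[EditingSiteCall]:
    """Emit calls supported by the per-replicate filter in >= min_replicates
    replicates (by default counted across both conditions together)."""
    calls = []
    for c in candidates:
        if within_condition:
            by_cond: dict[str, int] = {}
            for rep in c.candidate_replicates:
                cond = c.condition_of[rep]
                by_cond[cond] = by_cond.get(cond, 0) + 1
            support = max(by_cond.values(), default=0)
        else:
            support = len(c.candidate_replicates)
        if support < min_replicates:
            continue
        effs = {}
        for condition in ("fronds", "turions"):
            edited, total = c.pooled(condition)
            effs[condition] = compute_efficiency(edited, total) if total else None
        if effs["fronds"] is not None and effs["fronds"] == 100.0:
            logger.info(
                "site %d%s is edited in all reads; reference is plastome DNA, "
                "so this is still treated as an editing site, not a genomic SNV",
                c.genome_position, c.strand,
            )
        calls.append(
            EditingSiteCall(
                genome_position=c.genome_position,
                strand=c.strand,
                per_replicate=dict(c.per_replicate),
                condition_of=dict(c.condition_of),
                replicate_support=len(c.candidate_replicates),
                efficiency_fronds=effs["fronds"],
                efficiency_turions=effs["turions"],
            )
        )
    return calls


# -------------------------------------------------------------------- recovery


@dataclass
class RecoveryReport:
    true_positives: list[tuple[int, str]]
    false_positives: list[tuple[int, str]]
    false_negatives: list[tuple[int, str]]
    efficiency_errors_pct: dict[tuple[int, str], float]  # mean |est - true| over conditions

    @property
    def sensitivity(self) -> float:
        denom = len(self.true_positives) + len(self.false_negatives)
        return len(self.true_positives) / denom if denom else float("nan")

    @property
    def fdr(self) -> float:
        called = len(self.true_positives) + len(self.false_positives)
        return len(self.false_positives) / called if called else 0.0

    @property
    def mean_abs_efficiency_error_pct(self) -> float:
        vals = list(self.efficiency_errors_pct.values())
        return float(np.mean(vals)) if vals else float("nan")


def recover_sites(calls: Sequence[EditingSiteCall], truth) -> RecoveryReport:
    """Compare calls with the implanted ground truth (simulation mode)."""
    call_by_key = {(c.genome_position, c.strand): c for c in calls}
    truth_by_key = {(s.genome_position, s.transcribed_strand): s for s in truth}
    tp, fp, fn = [], [], []
    errors = {}
    for key, site in truth_by_key.items():
        if key in call_by_key:
            tp.append(key)
            c = call_by_key[key]
            errs = []
            for cond, true_eff in (
                ("fronds", site.efficiency_fronds),
                ("turions", site.efficiency_turions),
            ):
                est = {"fronds": c.efficiency_fronds, "turions": c.efficiency_turions}[cond]
                if est is not None:
                    errs.append(abs(est - 100.0 * true_eff))
            if errs:
                errors[key] = float(np.mean(errs))
        else:
            fn.append(key)
    for key in call_by_key:
        if key not in truth_by_key:
            fp.append(key)
    return RecoveryReport(
        true_positives=sorted(tp),
        false_positives=sorted(fp),
        false_negatives=sorted(fn),
        efficiency_errors_pct=errors,
    )


# ------------------------------------------------------------------------- IO


def write_calls_tsv(calls: Sequence[EditingSiteCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_position\tstrand\tfronds_edited\tfronds_total\tfronds_pct"
            "\tturions_edited\tturions_total\tturions_pct\treplicate_support\n"
        )
        for c in sorted(calls, key=lambda c: (c.genome_position, c.strand)):
            fe, ft = c.pooled("fronds")
            te, tt = c.pooled("turions")
            fp = round_percent(c.efficiency_fronds) if c.efficiency_fronds is not None else "."
            tp = round_percent(c.efficiency_turions) if c.efficiency_turions is not None else "."
            fh.write(
                f"{c.genome_position}\t{c.strand}\t{fe}\t{ft}\t{fp}"
                f"\t{te}\t{tt}\t{tp}\t{c.replicate_support}\n"
            )
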