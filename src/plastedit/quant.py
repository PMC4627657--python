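"""Expression quantification and differential tests.

Expression is summarized per gene as FPKM (fragments per kilobase of exon
per million mapped reads); with single-end libraries one fragment is one
read.  Differential expression is screened with Welch's t-test on
log2(FPKM + 1) across replicates, Benjamini-Hochberg FDR, and the joint
rule |fold change| > 2 and FDR < 0.05.  Differential editing between the
two conditions is tested per site with Pearson's chi-squared on the 2x2
table [edited, unedited] x [fronds, turions] (1 df, no continuity
correction), on counts pooled over each condition's replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def fpkm(fragments: int, exon_length: int, total_mapped: int) -> float:
    """fragments * 1e9 / (exon_length * total_mapped)."""
    if exon_length <= 0:
        raise ValueError("exon_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return fragments * 1e9 / (exon_length * total_mapped)


def count_fragments(alignments, genes) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene, per-replicate fragment counts from strand-matched overlap.

    A read is assigned to every gene whose exons its aligned segments
    overlap on the matching strand (plastid genes are dense; a read over a
    boundary supports both neighbours).  Also returns total mapped reads
    per replicate (the FPKM denominator).
    """
    counts: dict[str, dict[str, int]] = {g.name: {} for g in genes}
    totals: dict[str, int] = {}
    for aln in alignments:
        totals[aln.replicate_id] = totals.get(aln.replicate_id, 0) + 1
        for g in genes:
            if g.strand != aln.strand:
                continue
            hit = False
            for gstart0, _, ln in aln.segments:
                a_lo, a_hi = gstart0 + 1, gstart0 + ln  # 1-based inclusive
                for s, e in g.exons:
                    if a_lo <= e and s <= a_hi:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                counts[g.name][aln.replicate_id] = counts[g.name].get(aln.replicate_id, 0) + 1
    reps = sorted(totals)
    df = pd.DataFrame(
        {rep: [counts[g.name].get(rep, 0) for g in genes] for rep in reps},
        index=[g.name for g in genes],
    )
    return df, totals


def expression_table(
    fragment_counts: pd.DataFrame,
    exon_lengths: dict[str, int],
    total_mapped: dict[str, int],
    condition_of: dict[str, str],
) -> pd.DataFrame:
    """Per-replicate FPKM plus condition means and turions/fronds fold change."""
    reps = list(fragment_counts.columns)
    out = pd.DataFrame(index=fragment_counts.index)
    for rep in reps:
        out[f"count_{rep}"] = fragment_counts[rep]
        out[f"fpkm_{rep}"] = [
            fpkm(int(c), exon_lengths[g], total_mapped[rep])
            for g, c in fragment_counts[rep].items()
        ]
    for cond in ("fronds", "turions"):
        cols = [f"fpkm_{r}" for r in reps if condition_of[r] == cond]
        out[f"mean_fpkm_{cond}"] = out[cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["mean_fpkm_turions"] / out["mean_fpkm_fronds"]
    defined = (out["mean_fpkm_fronds"] > 0) & (out["mean_fpkm_turions"] > 0)
    out["fold_change"] = ratio.where(defined)
    out["log2_fold_change"] = np.log2(ratio.where(defined))
    return out


def differential_expression(
    expression: pd.DataFrame,
    condition_of: dict[str, str],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag genes with |fold change| > threshold and BH-FDR < threshold.

    P-values come from Welch's t-test on log2(FPKM + 1) across replicates.
    """
    fronds_reps = [r for r, c in condition_of.items() if c == "fronds"]
    turions_reps = [r for r, c in condition_of.items() if c == "turions"]
    if len(fronds_reps) < 2 or len(turions_reps) < 2:
        raise ValueError("differential expression requires >= 2 replicates per condition")
    xf = np.log2(expression[[f"fpkm_{r}" for r in fronds_reps]].to_numpy() + 1.0)
    xt = np.log2(expression[[f"fpkm_{r}" for r in turions_reps]].to_numpy() + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        res = stats.ttest_ind(xt, xf, axis=1, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    out = expression.copy()
    out["p_value"] = p
    out["fdr"] = multipletests(p, method="fdr_bh")[1]
    fc = out["fold_change"]
    passes_fc = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    out["flagged"] = passes_fc.fillna(False) & (out["fdr"] < fdr_threshold)
    return out


# ----------------------------------------------------------- differential editing


@dataclass
class DifferentialEditingRecord:
    genome_position: int
    strand: str
    fronds: tuple[int, int]  # (edited, total)
    turions: tuple[int, int]
    chi2_statistic: float
    p_value: float
    significant: bool = False


def chi2_editing(
    fronds: tuple[int, int], turions: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    [edited, unedited] x [fronds, turions].

    Degenerate tables (a zero row or column sum) return (0.0, 1.0).
    """
    ef, tf = fronds
    et, tt = turions
    if not (0 <= ef <= tf and 0 <= et <= tt):
        raise ValueError("edited counts must lie in [0, total]")
    a, b = ef, tf - ef  # fronds: edited, unedited
    c, d = et, tt - et  # turions
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        logger.warning("degenerate 2x2 editing table %s vs %s; p set to 1", fronds, turions)
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def differential_editing(calls: Iterable, alpha: float = 0.05) -> list[DifferentialEditingRecord]:
    """Chi-squared differential-editing test for every call with reads in
    both conditions."""
    records = []
    for call in calls:
        fronds = call.pooled("fronds")
        turions = call.pooled("turions")
        if fronds[1] == 0 or turions[1] == 0:
            continue
        stat, p = chi2_editing(fronds, turions)
        records.append(
            DifferentialEditingRecord(
                genome_position=call.genome_position,
                strand=call.strand,
                fronds=fronds,
                turions=turions,
                chi2_statistic=stat,
                p_value=p,
                significant=p < alpha,
            )
        )
    return records


def significant_sites(
    records: Sequence[DifferentialEditingRecord],
    alpha: float = 0.05,
    correction: str = "none",
) -> list[DifferentialEditingRecord]:
    """Records passing the significance criterion, sorted by genome position.

    ``correction='BH'`` applies Benjamini-Hochberg across the record set
    before thresholding at ``alpha``.
    """
    if not records:
        return []
    if correction == "none":
        kept = [r for r in records if r.p_value < alpha]
    elif correction == "BH":
        reject = multipletests([r.p_value for r in records], alpha=alpha, method="fdr_bh")[0]
        kept = [r for r, rej in zip(records, reject) if rej]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    for r in kept:
        r.significant = True
    return sorted(kept, key=lambda r: r.genome_position)
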