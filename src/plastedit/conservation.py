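"""Cross-species editing-site conservation and study-level summaries.

Each editing site of the focal species is assigned a state per comparison
species: ``+`` (experimentally edited there too), ``T`` (pre-edited: the
genome already encodes T), ``?`` (C present, editome never assayed),
``-`` (C present, assayed, not edited) and ``NA`` (gene absent or position
not alignable).  Shared-site fractions are computed over coding-region
rows only, with ``NA`` cells excluded from the denominator; this is the
convention under which the published ndh-family counts are reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import SPECIES, STATES

logger = logging.getLogger(__name__)


def infer_state(
    aligned_base: str,
    *,
    gene_present: bool = True,
    edited: bool | None = None,
) -> str:
    """State of a homologous position in a comparison species.

    ``aligned_base`` is the DNA base (or '-' for a gap) at the position
    homologous to the focal editing site.  ``edited`` is True if the
    species' editome records editing there, False if the editome was
    assayed and does not, None if no editome is available.
    """
    if not gene_present or aligned_base in ("-", ""):
        return "NA"
    base = aligned_base.upper()
    if base == "T":
        return "T"
    if base == "C":
        if edited is True:
            return "+"
        if edited is False:
            return "-"
        return "?"
    if base in ("A", "G"):
        logger.warning(
            "homologous base %s at an editing site: divergent codon, state NA", base
        )
        return "NA"
    raise ValueError(f"unexpected aligned base {aligned_base!r}")


def states_from_alignment(
    columns: Mapping[str, str],
    edit_status: Mapping[str, bool | None],
    present: Mapping[str, bool] | None = None,
) -> dict[str, str]:
    """Apply :func:`infer_state` across species for one aligned column."""
    present = present or {}
    return {
        sp: infer_state(
            base,
            gene_present=present.get(sp, True),
            edited=edit_status.get(sp),
        )
        for sp, base in columns.items()
    }


def state_matrix(fixture: pd.DataFrame, species: Sequence[str] = SPECIES) -> pd.DataFrame:
    """Site x species editing-state matrix from an annotated site table."""
    cols = ["site", "gene", "region", "genome_position", *species]
    matrix = fixture[cols].copy()
    for sp in species:
        bad = ~matrix[sp].isin(STATES)
        if bad.any():
            raise ValueError(f"invalid states in column {sp}: {matrix.loc[bad, sp].tolist()}")
    return matrix


def shared_sites(
    matrix: pd.DataFrame, species: str, gene_subset: Iterable[str]
) -> tuple[int, int, float]:
    """(shared, eligible, fraction) of the focal species' coding sites that
    the comparison species also edits, over a gene subset.

    Eligible rows are coding-region sites in the subset whose state is not
    NA; shared rows have state '+'.
    """
    if species not in matrix.columns:
        raise KeyError(f"species {species!r} not in matrix")
    subset = set(gene_subset)
    rows = matrix[
        matrix["gene"].isin(subset)
        & (matrix["region"] == "CDS")
        & (matrix[species] != "NA")
    ]
    eligible = len(rows)
    if eligible == 0:
        raise ValueError(f"no eligible sites for {species} over {sorted(subset)}")
    shared = int((rows[species] == "+").sum())
    return shared, eligible, shared / eligible


def classify_pattern(states: Mapping[str, str], species_order: Sequence[str]) -> str:
    """Conservation pattern of one site across the listed species.

    * ``conserved_all`` - edited (+) in every listed species;
    * ``conserved_subset:{...}`` - edited in a proper, non-empty subset;
    * ``focal_specific`` - edited nowhere else, every other state T or -
      (the comparison genomes encode T or are assayed unedited);
    * ``unresolved`` - edited nowhere else but some states are untested (?)
      or unalignable (NA).
    """
    vals = [states[sp] for sp in species_order]
    shared = [sp for sp, v in zip(species_order, vals) if v == "+"]
    if shared and len(shared) == len(species_order):
        return "conserved_all"
    if shared:
        return "conserved_subset:{" + ",".join(shared) + "}"
    if all(v in ("T", "-") for v in vals):
        return "focal_specific"
    return "unresolved"


@dataclass
class SummaryStats:
    n_sites: int
    n_genes: int
    mean_efficiency_fronds: float  # percent
    mean_efficiency_turions: float
    codon_position_counts: tuple[int, int, int]
    n_noncoding: int
    per_gene_site_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_genes": self.n_genes,
            "mean_efficiency_fronds": self.mean_efficiency_fronds,
            "mean_efficiency_turions": self.mean_efficiency_turions,
            "codon_position_counts": list(self.codon_position_counts),
            "n_noncoding": self.n_noncoding,
            "per_gene_site_counts": self.per_gene_site_counts,
        }


def summarize(sites: pd.DataFrame) -> SummaryStats:
    """Study-level summary of an annotated site table.

    Expects columns ``gene``, ``region``, ``gene_position``, ``fronds_pct``
    and ``turions_pct``.  Mean efficiency is the arithmetic mean of
    per-site percents; codon-position counts derive from the gene position
    modulo 3 over coding rows; gene counts span all non-intergenic sites.
    """
    if sites.empty:
        return SummaryStats(0, 0, 0.0, 0.0, (0, 0, 0), 0, {})
    coding = sites[sites["region"] == "CDS"]
    offsets = ((coding["gene_position"].astype(int) - 1) % 3) + 1
    codon_counts = tuple(int((offsets == k).sum()) for k in (1, 2, 3))
    named = sites[sites["gene"].notna()]
    per_gene = named.groupby("gene").size().to_dict()
    return SummaryStats(
        n_sites=len(sites),
        n_genes=named["gene"].nunique(),
        mean_efficiency_fronds=float(sites["fronds_pct"].mean()),
        mean_efficiency_turions=float(sites["turions_pct"].mean()),
        codon_position_counts=codon_counts,  # type: ignore[arg-type]
        n_noncoding=int((sites["region"] != "CDS").sum()),
        per_gene_site_counts={k: int(v) for k, v in sorted(per_gene.items())},
    )
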