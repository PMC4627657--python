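"""Packaged reference table of the 66 Spirodela chloroplast editing sites.

The table ships as a TSV mirroring the published layout: one row per
C-to-U editing site with its genome position, spliced-CDS position and
codon context (edited base uppercase, e.g. ``cCa``), the measured editing
efficiency in fronds and turions (integer percent), and the editing state
of the homologous position in six other species:

======  =====================================================
state   meaning
======  =====================================================
``+``   experimentally determined editing site
``T``   pre-edited: the genome already encodes T
``?``   C present but editing status never assayed
``-``   C present, editome assayed, not edited
``NA``  gene absent / position not alignable
======  =====================================================

The loader normalizes each row with a parsed gene name and a region class
(CDS, intron, 5'UTR or intergenic) and validates structural integrity.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

SPECIES = ["Cn", "Os", "Zm", "At", "Nt", "Sl"]
STATES = {"+", "T", "?", "-", "NA"}

#: Sites reported as having significantly different editing efficiency
#: between fronds and turions (seven genes, eleven sites).
TABLE2_SITES = [
    "5'UTR rps7-1",
    "ndhB-15",
    "ndhC-1",
    "ndhC-2",
    "ndhC-3",
    "ndhD-1",
    "rpoB-1",
    "rps3",
    "rps7-2",
    "ycf3-1",
    "ycf3-5",
]

_SUFFIX = re.compile(r"-(\d+)$")


class FixtureIntegrityError(ValueError):
    """The packaged site table failed a structural check."""


def _parse_site_label(label: str) -> tuple[str | None, str]:
    """Return (gene, region) from a printed site label."""
    if label.startswith("intergenic"):
        return None, "intergenic"
    if label.startswith("5'UTR"):
        core = label.split(None, 1)[1]
        return _SUFFIX.sub("", core), "5'UTR"
    if label.endswith("intron"):
        core = label.rsplit(None, 1)[0]
        return _SUFFIX.sub("", core), "intron"
    return _SUFFIX.sub("", label), "CDS"


def load_table1_fixture() -> pd.DataFrame:
    """Load and validate the packaged editing-site table.

    Returns a DataFrame with one row per site and derived columns
    ``gene`` and ``region`` alongside the printed ones.
    """
    with resources.files("plastedit.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)

    expected = {"site", "genome_position", "gene_position", "codon", "aa_change",
                "fronds_pct", "turions_pct", *SPECIES}
    missing = expected - set(df.columns)
    if missing:
        raise FixtureIntegrityError(f"fixture missing columns: {sorted(missing)}")

    genes, regions = zip(*(_parse_site_label(s) for s in df["site"]))
    df["gene"] = genes
    df["region"] = regions
    df["genome_position"] = df["genome_position"].astype(int)
    df["gene_position"] = df["gene_position"].replace("-", pd.NA).astype("Int64")
    for col in ("fronds_pct", "turions_pct"):
        df[col] = df[col].astype(int)

    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    if len(df) != 66:
        raise FixtureIntegrityError(f"expected 66 rows, found {len(df)}")
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        for col in ("fronds_pct", "turions_pct"):
            if not 0 <= row[col] <= 100:
                raise FixtureIntegrityError(f"row {rowno}: {col}={row[col]} outside 0..100")
        for sp in SPECIES:
            if row[sp] not in STATES:
                raise FixtureIntegrityError(f"row {rowno}: bad state {row[sp]!r} for {sp}")
        if row["region"] == "CDS":
            codon = row["codon"]
            if sum(c.isupper() for c in codon) != 1 or len(codon) != 3:
                raise FixtureIntegrityError(f"row {rowno}: malformed codon {codon!r}")
            if pd.isna(row["gene_position"]):
                raise FixtureIntegrityError(f"row {rowno}: coding row lacks gene position")
        else:
            if row["codon"] != "-":
                raise FixtureIntegrityError(f"row {rowno}: non-coding row carries a codon")
    n_noncoding = int((df["region"] != "CDS").sum())
    if n_noncoding != 8:
        raise FixtureIntegrityError(f"expected 8 non-coding rows, found {n_noncoding}")


def load_table2_sites(table1: pd.DataFrame | None = None) -> pd.DataFrame:
    """The eleven differentially edited sites with their per-condition percents."""
    df = table1 if table1 is not None else load_table1_fixture()
    sub = df[df["site"].isin(TABLE2_SITES)].copy()
    if len(sub) != len(TABLE2_SITES):
        raise FixtureIntegrityError("differential-site labels do not all match the table")
    return sub[["site", "gene", "genome_position", "fronds_pct", "turions_pct"]].reset_index(drop=True)
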