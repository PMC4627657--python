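"""End-to-end pipeline: configuration, stage composition and reporting.

Two modes exist.  ``simulate`` runs the full chain on synthetic data
(plastome -> reads -> QC -> placement -> pileup -> calling -> annotation ->
expression and differential tests) and additionally scores recovery
against the implanted truth.  ``fixture`` loads the packaged reference
editing-site table and reproduces its summary, conservation and
differential-editing views without sequencing data.

Every stage logs its effective parameters and in/out counts to ``run.log``;
re-running with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, calling, conservation, fixtures, quant, simulate
from .genes import write_gff3
from .ingest import build_pileup, place_reads, qc_filter


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # 'simulate' or 'fixture'
    # simulation
    genome_length: int = 15_000
    gene_count: int = 20
    intron_fraction: float = 0.15
    n_replicates_per_condition: int = 4
    mean_coverage: float = 200.0
    read_length: int = 100
    error_rate: float = 0.001
    low_quality_read_fraction: float = 0.05
    n_sites: int = 66
    efficiency_source: str = "fixture"  # 'fixture' or 'uniform'
    n_intron_sites: int = 2
    n_utr_sites: int = 1
    n_intergenic_sites: int = 5
    # thresholds
    min_mean_quality: float = 20.0
    min_length: int = 70
    min_coverage: int = 10
    min_edited_reads: int = 2
    min_replicates: int = 2
    alpha: float = 0.05
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_coverage < 1 or self.min_edited_reads < 1 or self.min_replicates < 1:
            raise ValueError("caller thresholds must be >= 1")

    # flat key-value round trip
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            genome_length=self.genome_length,
            gene_count=self.gene_count,
            intron_fraction=self.intron_fraction,
            n_replicates_per_condition=self.n_replicates_per_condition,
            mean_coverage=self.mean_coverage,
            read_length=self.read_length,
            error_rate=self.error_rate,
            low_quality_read_fraction=self.low_quality_read_fraction,
            seed=self.seed,
        )


NDH_SUBSET = ("ndhA", "ndhB", "ndhD", "ndhF")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _RunLog:
    def __init__(self):
        self.lines: list[str] = []

    def stage(self, name: str, **params) -> None:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        self.lines.append(f"[{name}] {kv}")

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the summary dict written to summary.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    log.stage("config", **dataclasses.asdict(config))
    try:
        if config.mode == "fixture":
            summary = _run_fixture(config, out, log)
        else:
            summary = _run_simulation(config, out, log)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(config.mode, exc) from exc
    config.to_yaml(out / "config.yaml")
    log.write(out / "run.log")
    _json_dump(summary, out / "summary.json")
    return summary


def _fixture_efficiencies(n_sites: int) -> list[tuple[float, float]]:
    table = fixtures.load_table1_fixture()
    pairs = [
        (f / 100.0, t / 100.0)
        for f, t in zip(table["fronds_pct"], table["turions_pct"])
    ]
    if n_sites > len(pairs):
        raise ValueError(f"fixture provides only {len(pairs)} efficiency pairs")
    return pairs[:n_sites]


def _run_simulation(config: PipelineConfig, out: Path, log: _RunLog) -> dict:
    sim_cfg = config.simulation_config()

    try:
        genome, genes = simulate.build_synthetic_plastome(sim_cfg)
        noncoding = {
            "intron": config.n_intron_sites,
            "5'UTR": config.n_utr_sites,
            "intergenic": config.n_intergenic_sites,
        }
        effs = (
            _fixture_efficiencies(config.n_sites)
            if config.efficiency_source == "fixture"
            else None
        )
        truth = simulate.implant_editing_sites(
            genome, genes, config.n_sites, effs, noncoding=noncoding, seed=config.seed
        )
        simulate.write_fasta(genome, out / "genome.fa")
        write_gff3(genes, out / "genes.gff3")
        simulate.write_truth(truth, out / "truth.tsv")
        reads_by_rep = simulate.simulate_experiment(genome, truth, sim_cfg)
        log.stage(
            "simulate",
            genome_length=len(genome),
            genes=len(genes),
            sites=len(truth),
            reads=sum(len(v) for v in reads_by_rep.values()),
            seed=config.seed,
        )
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        alignments = []
        for rep_id, reads in reads_by_rep.items():
            kept, qc = qc_filter(reads, config.min_mean_quality, config.min_length)
            aln, placement = place_reads(kept, genome)
            log.stage(
                "ingest",
                replicate=rep_id,
                total=qc.total,
                qc_pass=qc.passing,
                qc_pct=f"{qc.percent_passing:.1f}",
                placed=placement.placed,
                unmapped=placement.unmapped_malformed + placement.unmapped_divergent,
            )
            alignments.extend(aln)
        pileups = build_pileup(alignments, genome)
        log.stage("pileup", replicates=len(pileups.replicate_ids), bases=pileups.total_bases())
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    try:
        result = calling.call_candidates(
            pileups, genome, genes,
            min_coverage=config.min_coverage,
            min_edited_reads=config.min_edited_reads,
        )
        calls = calling.apply_replicate_filter(result.candidates, config.min_replicates)
        sites_df = annotate.annotate_calls(calls, genes, genome)
        sites_df.to_csv(out / "sites.tsv", sep="\t", index=False)
        log.stage(
            "call",
            min_coverage=config.min_coverage,
            min_edited_reads=config.min_edited_reads,
            min_replicates=config.min_replicates,
            candidates=len(result.candidates),
            calls=len(calls),
            non_canonical=len(result.non_canonical),
        )
    except Exception as exc:
        raise StageError("call", exc) from exc

    try:
        condition_of = {rep: reads_by_rep[rep][0].condition for rep in reads_by_rep}
        counts, totals = quant.count_fragments(alignments, genes)
        exon_lengths = {g.name: g.exon_length for g in genes}
        expr = quant.expression_table(counts, exon_lengths, totals, condition_of)
        expr = quant.differential_expression(
            expr, condition_of, config.fc_threshold, config.fdr_threshold
        )
        expr.to_csv(out / "expression.tsv", sep="\t")
        de_records = quant.differential_editing(calls, alpha=config.alpha)
        sig = quant.significant_sites(de_records, alpha=config.alpha)
        _write_differential(de_records, out / "differential.tsv", config.alpha)
        log.stage(
            "diff",
            alpha=config.alpha,
            de_genes=int(expr["flagged"].sum()),
            editing_tested=len(de_records),
            editing_significant=len(sig),
        )
    except Exception as exc:
        raise StageError("diff", exc) from exc

    try:
        stats = conservation.summarize(sites_df)
        report = calling.recover_sites(calls, truth)
        summary = {
            "mode": "simulate",
            "summary": stats.to_dict(),
            "n_calls": len(calls),
            "recovery": {
                "true_positives": len(report.true_positives),
                "false_positives": len(report.false_positives),
                "false_negatives": len(report.false_negatives),
                "sensitivity": report.sensitivity,
                "fdr": report.fdr,
                "mean_abs_efficiency_error_pct": report.mean_abs_efficiency_error_pct,
            },
            "differential_editing_significant": len(sig),
            "differential_expression_flagged": int(expr["flagged"].sum()),
        }
        log.stage(
            "summarize",
            sites=stats.n_sites,
            recovered=len(report.true_positives),
            false_positives=len(report.false_positives),
        )
        return summary
    except Exception as exc:
        raise StageError("summarize", exc) from exc


def _run_fixture(config: PipelineConfig, out: Path, log: _RunLog) -> dict:
    try:
        table = fixtures.load_table1_fixture()
    except Exception as exc:
        raise StageError("fixture", exc) from exc
    table.to_csv(out / "sites.tsv", sep="\t", index=False)

    matrix = conservation.state_matrix(table)
    matrix.to_csv(out / "states.tsv", sep="\t", index=False)

    diff = fixtures.load_table2_sites(table)
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)

    consistency = annotate.annotate_fixture(table)
    stats = conservation.summarize(table)
    shared = {
        sp: conservation.shared_sites(matrix, sp, NDH_SUBSET)
        for sp in ("Cn", "Os", "Zm")
    }
    ndh_b = matrix[(matrix["gene"] == "ndhB") & (matrix["region"] == "CDS")]
    patterns = [
        conservation.classify_pattern(
            {sp: row[sp] for sp in ("Cn", "Os", "Zm")}, ("Cn", "Os", "Zm")
        )
        for _, row in ndh_b.iterrows()
    ]
    summary = {
        "mode": "fixture",
        "summary": stats.to_dict(),
        "fixture_consistency": {
            "n_checked": consistency.n_checked,
            "n_matched": consistency.n_matched,
            "mismatches": [dataclasses.asdict(m) for m in consistency.mismatches],
        },
        "ndh_shared_sites": {
            sp: {"shared": s, "eligible": e, "percent": round(100 * f)}
            for sp, (s, e, f) in shared.items()
        },
        "ndhB_patterns": {p: patterns.count(p) for p in sorted(set(patterns))},
        "differential_sites": diff["site"].tolist(),
    }
    log.stage(
        "fixture",
        sites=stats.n_sites,
        genes=stats.n_genes,
        noncoding=stats.n_noncoding,
        consistency=f"{consistency.n_matched}/{consistency.n_checked}",
    )
    return summary


def _write_differential(records, path: Path, alpha: float) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_position\tstrand\tfronds_edited\tfronds_total"
            "\tturions_edited\tturions_total\tchi2\tp_value\tsignificant\n"
        )
        for r in sorted(records, key=lambda r: (r.genome_position, r.strand)):
            fh.write(
                f"{r.genome_position}\t{r.strand}\t{r.fronds[0]}\t{r.fronds[1]}"
                f"\t{r.turions[0]}\t{r.turions[1]}\t{r.chi2_statistic:.6g}"
                f"\t{r.p_value:.6g}\t{int(r.p_value < alpha)}\n"
            )


# ---------------------------------------------------------------------- report


def render_report(outdir: str | Path) -> str:
    """Human-readable report; every number is re-derived from the TSVs."""
    out = Path(outdir)
    lines: list[str] = ["plastedit report", "================", ""]

    sites = pd.read_csv(out / "sites.tsv", sep="\t")
    stats = conservation.summarize(sites)
    lines.append(f"Editing sites: {stats.n_sites} sites in {stats.n_genes} genes")
    if stats.n_sites == 0:
        lines.append("0 sites called.")
    else:
        c1, c2, c3 = stats.codon_position_counts
        lines.append(
            f"  codon positions (1st/2nd/3rd): {c1}/{c2}/{c3}; "
            f"non-coding: {stats.n_noncoding}"
        )
        lines.append(
            f"  mean efficiency: fronds {round(stats.mean_efficiency_fronds)}%, "
            f"turions {round(stats.mean_efficiency_turions)}%"
        )
    lines.append("")

    diff_path = out / "differential.tsv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, sep="\t")
        if "significant" in diff.columns:
            sig = diff[diff["significant"] == 1]
            lines.append(f"Differential editing: {len(sig)} significant sites")
            for r in sig.itertuples():
                fp = round(100 * r.fronds_edited / r.fronds_total)
                tp = round(100 * r.turions_edited / r.turions_total)
                lines.append(
                    f"  pos {r.genome_position}{r.strand}: fronds {fp}% vs turions {tp}%"
                    f" (chi2={r.chi2:.1f}, p={r.p_value:.2g})"
                )
        else:
            lines.append(f"Differential editing: {len(diff)} significant sites")
            for r in diff.itertuples():
                lines.append(
                    f"  {r.site}: fronds {r.fronds_pct}% vs turions {r.turions_pct}%"
                )
        lines.append("")

    states_path = out / "states.tsv"
    if states_path.exists():
        matrix = pd.read_csv(states_path, sep="\t")
        lines.append("ndh-family shared editing sites:")
        for sp in ("Cn", "Os", "Zm"):
            if sp in matrix.columns:
                s, e, f = conservation.shared_sites(matrix, sp, NDH_SUBSET)
                lines.append(f"  {sp}: {s}/{e} ({round(100 * f)}%)")
        lines.append("")

    return "\n".join(lines)
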