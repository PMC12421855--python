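"""Orchestration: scan a genome directory into deterministic reports.

``run_scan`` drives parse -> release-factor selection -> premature-stop
classification -> per-genome statistics -> stop-identity census -> logo
matrix -> group comparison, writing TSV/JSON reports whose percentages are
always recomputable from the raw counts in the same files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .genome_io import (
    FormatError,
    GenomeRecord,
    filter_genomes_by_contamination,
    read_genome_annotation,
    select_release_factor_gene,
)
from .genome_stats import genome_stats_row, rows_to_dataframe
from .logo import build_logo
from .motif_scan import MotifParams, classify_prfb, report_row, REPORT_COLUMNS
from .stats_compare import aggregate_by_taxon, random_subset, welch_t_test, SUBSET_PRNG

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "PipelineError", "run_scan"]


class PipelineError(RuntimeError):
    """Fatal pipeline condition (e.g. no scannable genome in the input)."""


@dataclass
class RunConfig:
    """Everything a scan run needs; validated before the run starts."""

    input_dir: Path
    out_dir: Optional[Path] = None
    format: str = "genbank"  # or "gff3"
    target_gene: str = "prfB"
    motif_params: MotifParams = field(default_factory=MotifParams)
    table_override: Optional[int] = None
    max_contamination: Optional[float] = None
    subset_n: Optional[int] = None
    subset_seed: int = 0
    taxon_rank: str = "phylum"

    def validate(self) -> None:
        self.input_dir = Path(self.input_dir)
        if not self.input_dir.is_dir():
            raise PipelineError(f"input_dir {self.input_dir} is not a directory")
        if self.target_gene not in {"prfB", "prfA"}:
            raise PipelineError("target_gene must be prfB or prfA")
        if self.max_contamination is not None and self.max_contamination < 0:
            raise PipelineError("max_contamination must be non-negative")
        if self.subset_n is not None and self.subset_n <= 0:
            raise PipelineError("subset_n must be positive")
        p = self.motif_params
        if p.upstream < 0 or p.downstream < 0 or p.min_spacer < 0 or p.max_spacer < p.min_spacer:
            raise PipelineError("motif window/spacer parameters out of range")


@dataclass
class ScanResult:
    genes: pd.DataFrame  # one row per genome, per-gene report columns
    stats: pd.DataFrame  # per-genome statistics
    census: dict
    taxon_table: pd.DataFrame
    comparison: dict
    logo_matrix: Optional[object]  # LogoMatrix or None when no motif windows
    calls: dict  # accession -> FrameshiftCall
    n_parse_failures: int


def _discover(config: RunConfig) -> list:
    if config.format == "genbank":
        files = sorted(
            p for p in config.input_dir.iterdir()
            if p.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}
        )
        return [(p, None) for p in files]
    pairs = []
    for gff in sorted(config.input_dir.glob("*.gff3")) + sorted(config.input_dir.glob("*.gff")):
        for ext in (".fa", ".fasta", ".fna"):
            fa = gff.with_suffix(ext)
            if fa.exists():
                pairs.append((gff, fa))
                break
        else:
            log.warning("%s: no matching FASTA; skipped", gff)
    return pairs


def _census(calls: dict) -> dict:
    statuses = [c.status for c in calls.values()]
    n = len(statuses)
    n_fs = statuses.count("frameshift")
    n_no = statuses.count("no_frameshift")
    n_scannable = n_fs + n_no
    identities = {"TAA": 0, "TAG": 0, "TGA": 0}
    for c in calls.values():
        if c.status == "frameshift" and c.primary_motif is not None:
            identities[c.primary_motif.stop.identity] += 1
    census = {
        "n_genomes": n,
        "n_frameshift": n_fs,
        "n_no_frameshift": n_no,
        "n_gene_absent": statuses.count("gene_absent"),
        "n_unscannable": statuses.count("unscannable"),
        "n_scannable": n_scannable,
        "percent_frameshift": (100.0 * n_fs / n_scannable) if n_scannable else None,
        "stop_identity_counts": identities,
        "stop_identity_percent": (
            {s: 100.0 * k / n_fs for s, k in identities.items()} if n_fs else None
        ),
    }
    return census


def _comparison(stats: pd.DataFrame, subset_n: Optional[int], subset_seed: int) -> dict:
    """Welch comparisons of GC and terminal TGA usage, motif vs no-motif."""
    comp: dict = {"subset_n": subset_n, "subset_seed": subset_seed, "prng": SUBSET_PRNG}
    df = stats[stats["prfb_status"].isin(["frameshift", "no_frameshift"])]
    if subset_n is not None and subset_n < len(df):
        keep = set(random_subset(list(df["accession"]), subset_n, subset_seed))
        df = df[df["accession"].isin(keep)]
        comp["n_after_subset"] = len(df)
    fs = df[df["prfb_status"] == "frameshift"]
    no = df[df["prfb_status"] == "no_frameshift"]
    comp["n_frameshift"] = len(fs)
    comp["n_no_frameshift"] = len(no)
    for metric in ("gc_fraction", "frac_TGA"):
        x = fs[metric].dropna().to_numpy()
        y = no[metric].dropna().to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            comp[metric] = welch_t_test(x, y).to_dict()
        else:
            comp[metric] = None
    return comp


def run_scan(config: RunConfig) -> ScanResult:
    """Run the full scan over a genome directory; write reports if out_dir set.

    Per-genome parse failures are logged and tallied; the run is fatal only
    when zero genomes are scannable.
    """
    config.validate()
    sources = _discover(config)
    genomes: list = []
    n_fail = 0
    for path, fasta in sources:
        try:
            g = read_genome_annotation(path, format=config.format, fasta=fasta)
            genomes.append(g)
        except (FormatError, FileNotFoundError, ValueError) as exc:
            log.warning("%s: parse failure: %s", path, exc)
            n_fail += 1
    if config.max_contamination is not None:
        genomes = filter_genomes_by_contamination(genomes, config.max_contamination)
    genomes.sort(key=lambda g: g.accession)

    calls: dict = {}
    gene_rows = []
    stat_rows = []
    windows = []
    for g in genomes:
        selection = select_release_factor_gene(g, config.target_gene)
        call = classify_prfb(selection.gene, config.motif_params, config.table_override)
        if selection.ambiguous:
            call.notes.append("ambiguous gene selection; first by coordinate used")
        calls[g.accession] = call
        gene_rows.append(
            report_row(g.accession, selection.gene.gene_name if selection.gene else "", call)
        )
        stat_rows.append(genome_stats_row(g, call))
        if call.status == "frameshift" and call.primary_motif is not None:
            windows.append((call.primary_motif.window_seq, call.primary_motif.window_anchor))

    if not genomes or all(
        c.status in {"gene_absent", "unscannable"} for c in calls.values()
    ):
        raise PipelineError("no scannable genomes in input")

    genes_df = pd.DataFrame(gene_rows, columns=REPORT_COLUMNS)
    stats_df = rows_to_dataframe(stat_rows)
    census = _census(calls)
    taxon_table = aggregate_by_taxon(stat_rows, rank=config.taxon_rank)
    comparison = _comparison(stats_df, config.subset_n, config.subset_seed)
    logo_matrix = None
    if windows:
        width = config.motif_params.upstream + config.motif_params.downstream + 1
        logo_matrix = build_logo(
            windows, width=width, anchor_position=config.motif_params.upstream
        )

    result = ScanResult(
        genes=genes_df,
        stats=stats_df,
        census=census,
        taxon_table=taxon_table,
        comparison=comparison,
        logo_matrix=logo_matrix,
        calls=calls,
        n_parse_failures=n_fail,
    )
    if config.out_dir is not None:
        _write_reports(config, result)
    return result


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "input_dir": str(config.input_dir),
            "format": config.format,
            "target_gene": config.target_gene,
            "motif_params": dataclasses.asdict(config.motif_params),
            "table_override": config.table_override,
            "max_contamination": config.max_contamination,
            "subset_n": config.subset_n,
            "subset_seed": config.subset_seed,
            "taxon_rank": config.taxon_rank,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_reports(config: RunConfig, result: ScanResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    result.stats.to_csv(out / "genome_stats.tsv", sep="\t", index=False, float_format="%.6g")
    result.taxon_table.to_csv(out / "taxon_summary.tsv", sep="\t", index=False,
                              float_format="%.6g")
    (out / "census.json").write_text(json.dumps(result.census, indent=1))
    (out / "comparison.json").write_text(json.dumps(result.comparison, indent=1))
    if result.logo_matrix is not None:
        result.logo_matrix.write_tsv(out / "logo_matrix.tsv")
        result.logo_matrix.write_json(out / "logo_matrix.json")
        with open(out / "motif_windows.fasta", "w") as fh:
            fs = result.genes[result.genes["status"] == "frameshift"]
            for _, row in fs.iterrows():
                fh.write(
                    f">{row['accession']} anchor={row['window_anchor']}\n"
                    f"{row['window_seq']}\n"
                )
    manifest = {
        "package": "prfbscan",
        "version": __version__,
        "config_hash": _config_hash(config),
        "subset_prng": SUBSET_PRNG,
        "subset_seed": config.subset_seed,
        "n_parse_failures": result.n_parse_failures,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
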