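"""End-to-end pipeline: ingest → blacklist → merge → dereplicate →
normalize → screen → export → stats, with a machine-readable derivation
report.

Two entry points: :func:`run_pipeline` works from a config pointing at files
on disk (the CLI ``run`` subcommand wraps it) and :func:`run_fixture_pipeline`
drives the same stages from an in-memory generated fixture, which is how the
test suite verifies planted ground truth without touching the filesystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .compare import DatabaseStats, db_stats
from .errors import CoirefError, StageError
from .exports import to_blast_inputs, to_kraken_fasta, to_megan_inputs
from .ingest import parse_bold_tsv, parse_genbank_flatfile
from .merge import dereplicate, filter_blacklist, merge, parse_blacklist
from .normalize import NormalizationReport, normalize_records, report_to_tsv
from .records import ReferenceDatabase
from .screen import Checklist, parse_checklist_tsv, screen_contaminants, screen_marine
from .simulate import Fixture, FixtureSpec, make_fixture
from .taxonomy import TaxonomyIndex, parse_taxonomy_dump, write_taxonomy_dump


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run.  All referenced paths must exist."""

    names_dmp: Path
    nodes_dmp: Path
    genbank_file: Optional[Path] = None
    bold_file: Optional[Path] = None
    blacklist: Optional[Path] = None
    marine_checklist: Optional[Path] = None
    contaminant_checklist: Optional[Path] = None
    contaminant_policy: str = "flag"
    gene_label: str = "COI"
    export_formats: tuple[str, ...] = ("kraken2", "megan", "blast")
    output_dir: Path = Path("coiref_output")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "names_dmp", "nodes_dmp", "genbank_file", "bold_file", "blacklist",
            "marine_checklist", "contaminant_checklist", "output_dir",
        ):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("contaminant_policy", "gene_label", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "export_formats" in raw:
            kwargs["export_formats"] = tuple(raw["export_formats"])
        return cls(**kwargs)

    def validate_paths(self) -> None:
        for key in (
            "names_dmp", "nodes_dmp", "genbank_file", "bold_file", "blacklist",
            "marine_checklist", "contaminant_checklist",
        ):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise StageError("config", f"{key} path does not exist: {p}")


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    db: ReferenceDatabase
    index: TaxonomyIndex
    normalization: NormalizationReport
    marine_summary: dict
    contaminant_report: dict
    stats: DatabaseStats
    exports: dict[str, dict[str, str]]
    derivation_report: dict


def _derivation_report(db: ReferenceDatabase, extra: dict) -> dict:
    report = {"steps": list(db.derivation_log), **extra}
    # count-chain consistency: each step's output feeds the next stage
    return report


def run_stages(
    index: TaxonomyIndex,
    genbank_text: str = "",
    bold_text: str = "",
    blacklist_text: str = "",
    marine_checklist: Optional[Checklist] = None,
    contaminant_checklist: Optional[Checklist] = None,
    contaminant_policy: str = "flag",
    gene_label: str = "COI",
) -> PipelineResult:
    """Run every stage over in-memory inputs (the engine behind both APIs)."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CoirefError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    gb_records, gb_report = stage(
        "ingest-genbank", parse_genbank_flatfile, genbank_text, gene_label
    )
    bold_records, bold_report = stage("ingest-bold", parse_bold_tsv, bold_text)
    blacklist = parse_blacklist(blacklist_text)
    gb_kept, gb_removed, unused_a = filter_blacklist(gb_records, blacklist)
    bold_kept, bold_removed, unused_b = filter_blacklist(bold_records, blacklist)
    unused = sorted(set(unused_a) & set(unused_b))
    db = stage("merge", merge, gb_kept, bold_kept)
    db.log_step(
        "blacklist",
        n_in=len(gb_records) + len(bold_records),
        n_out=len(gb_kept) + len(bold_kept),
        removed=gb_removed + bold_removed,
        unused_entries=unused,
    )
    db = stage("dereplicate", dereplicate, db)
    db, norm_report = stage("normalize", normalize_records, db, index)
    marine_summary: dict = {}
    if marine_checklist is not None:
        db, marine_summary = stage("screen-marine", screen_marine, db, marine_checklist, index)
    contaminant_report: dict = {}
    if contaminant_checklist is not None:
        db, contaminant_report = stage(
            "screen-contaminants",
            screen_contaminants,
            db,
            contaminant_checklist,
            contaminant_policy,
            index,
        )
    stats = stage("stats", db_stats, db)
    exports = {
        "kraken2": {"library.fasta": stage("export", to_kraken_fasta, db)},
    }
    megan_fasta, megan_map = stage("export", to_megan_inputs, db)
    exports["megan"] = {"normalized.fasta": megan_fasta, "acc2taxid.tsv": megan_map}
    blast_fasta, taxid_map = stage("export", to_blast_inputs, db)
    exports["blast"] = {"db.fasta": blast_fasta, "taxid_map.txt": taxid_map}

    derivation = _derivation_report(
        db,
        {
            "ingest": {
                "genbank_parsed": gb_report.n_parsed,
                "genbank_skipped": gb_report.n_skipped,
                "bold_parsed": bold_report.n_parsed,
                "bold_skipped": bold_report.n_skipped,
            },
            "stats": {
                "n_sequences": stats.n_sequences,
                "n_unique_species": stats.n_unique_species,
                "pct_unique_species": stats.pct_unique_species,
                "n_marine_species": stats.n_marine_species,
                "pct_marine_species": stats.pct_marine_species,
            },
        },
    )
    return PipelineResult(
        db=db,
        index=index,
        normalization=norm_report,
        marine_summary=marine_summary,
        contaminant_report=contaminant_report,
        stats=stats,
        exports=exports,
        derivation_report=derivation,
    )


def run_fixture_pipeline(
    spec: FixtureSpec, contaminant_policy: str = "remove"
) -> tuple[PipelineResult, Fixture]:
    """Generate a fixture and run the full pipeline over it in memory."""
    fixture = make_fixture(spec)
    index = parse_taxonomy_dump(fixture.names_text, fixture.nodes_text)
    result = run_stages(
        index,
        genbank_text=fixture.genbank_text,
        bold_text=fixture.bold_tsv,
        blacklist_text=fixture.blacklist_text,
        marine_checklist=fixture.marine_checklist,
        contaminant_checklist=fixture.contaminant_checklist,
        contaminant_policy=contaminant_policy,
    )
    return result, fixture


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based full run; writes exports and reports under output_dir."""
    config.validate_paths()

    def read(p: Optional[Path]) -> str:
        return Path(p).read_text() if p is not None else ""

    index = parse_taxonomy_dump(read(config.names_dmp), read(config.nodes_dmp))
    marine = (
        parse_checklist_tsv(read(config.marine_checklist), "marine")
        if config.marine_checklist
        else None
    )
    contaminants = (
        parse_checklist_tsv(read(config.contaminant_checklist), "contaminants")
        if config.contaminant_checklist
        else None
    )
    result = run_stages(
        index,
        genbank_text=read(config.genbank_file),
        bold_text=read(config.bold_file),
        blacklist_text=read(config.blacklist),
        marine_checklist=marine,
        contaminant_checklist=contaminants,
        contaminant_policy=config.contaminant_policy,
        gene_label=config.gene_label,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fmt in config.export_formats:
        fmt_dir = out / fmt
        fmt_dir.mkdir(exist_ok=True)
        for fname, text in result.exports.get(fmt, {}).items():
            (fmt_dir / fname).write_text(text)
    names_text, nodes_text = write_taxonomy_dump(result.index)
    (out / "names.dmp").write_text(names_text)
    (out / "nodes.dmp").write_text(nodes_text)
    (out / "normalization_report.tsv").write_text(report_to_tsv(result.normalization))
    (out / "derivation_report.json").write_text(
        json.dumps(result.derivation_report, indent=2, default=str) + "\n"
    )
    return result
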