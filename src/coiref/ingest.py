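"""Repository ingest: GenBank flatfiles, BOLD-style TSV exports, search terms.

All tests and the reference pipeline work from local files; live retrieval
from NCBI Entrez or the BOLD API is deliberately kept out of the tested
surface (see :mod:`coiref.adapters`).  The search-term builder reproduces the
query shape used for keyword retrieval of COI barcodes: taxon name AND gene
synonyms (CO1/COI/COX1/COXI) AND an upload-year window AND origin, with or
without "barcode" as an extra keyword (the BAR / NOBAR variants).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .errors import BoldFormatError, GenBankParseError
from .records import SeqRecord, clean_sequence

DEFAULT_GENE_SYNONYMS = ("CO1", "COI", "COX1", "COXI")


@dataclass
class IngestReport:
    """Parsed/skipped bookkeeping for one input file."""

    n_parsed: int = 0
    n_skipped: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def skip(self, ident: str, reason: str) -> None:
        self.n_skipped += 1
        self.skipped.append((ident, reason))


def parse_genbank_flatfile(
    text: str, gene_label: str = "COI"
) -> tuple[list[SeqRecord], IngestReport]:
    """Convert a concatenation of GenBank flatfile entries to records.

    Only the LOCUS, ACCESSION/VERSION, ORGANISM and ORIGIN blocks are
    required.  The accession is the versioned accession when present.
    Entries lacking an organism or a sequence, or whose sequence contains
    non-IUPAC letters, are skipped and reported; a truncated final entry
    (missing the ``//`` terminator) raises :class:`GenBankParseError`.
    """
    out: list[SeqRecord] = []
    report = IngestReport()
    stripped = text.rstrip()
    if stripped and stripped.splitlines()[-1].strip() != "//":
        raise GenBankParseError("truncated final entry: missing '//' terminator")
    try:
        for rec in SeqIO.parse(io.StringIO(text), "genbank"):
            ident = rec.id if rec.id and rec.id != "<unknown id>" else rec.name
            organism = (rec.annotations.get("organism") or "").strip()
            if not organism:
                report.skip(ident, "missing ORGANISM")
                continue
            try:
                raw = str(rec.seq)
            except UndefinedSequenceError:
                raw = ""
            if not raw:
                report.skip(ident, "missing ORIGIN")
                continue
            seq, ok = clean_sequence(raw)
            if not ok:
                report.skip(ident, "non-IUPAC characters in sequence")
                continue
            gene = gene_label
            for feat in rec.features:
                if feat.type in ("gene", "CDS") and "gene" in feat.qualifiers:
                    gene = feat.qualifiers["gene"][0]
                    break
            out.append(SeqRecord(ident, "genbank", organism, gene, seq))
            report.n_parsed += 1
    except ValueError as exc:  # biopython signals truncation etc. this way
        raise GenBankParseError(f"malformed GenBank flatfile: {exc}") from exc
    return out, report


BOLD_REQUIRED_COLUMNS = ("processid", "species_name", "markercode", "nucleotides")


def parse_bold_tsv(text: str) -> tuple[list[SeqRecord], IngestReport]:
    """Parse a BOLD-style specimen/sequence TSV export.

    The header must name processid, species_name, markercode and nucleotides
    (order free); a missing column raises :class:`BoldFormatError`.  The
    process ID serves as the accession.  Rows with empty nucleotides are
    skipped and counted; gap characters are stripped.  Rows without a
    species_name fall back to the genus column when one is present, keeping
    the record assignable at genus level.
    """
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in BOLD_REQUIRED_COLUMNS if c not in header]
    if missing:
        raise BoldFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    genus_col = next((c for c in ("genus_name", "genus") if c in header), None)

    out: list[SeqRecord] = []
    report = IngestReport()
    for row in reader:
        ident = (row.get("processid") or "").strip()
        raw = (row.get("nucleotides") or "").strip()
        if not raw:
            report.skip(ident, "empty nucleotides")
            continue
        seq, ok = clean_sequence(raw)
        if not ok:
            report.skip(ident, "non-IUPAC characters in nucleotides")
            continue
        organism = (row.get("species_name") or "").strip()
        if not organism and genus_col:
            organism = (row.get(genus_col) or "").strip()
        if not organism or not ident:
            report.skip(ident or "<no processid>", "missing name or processid")
            continue
        gene = (row.get("markercode") or "").strip()
        out.append(SeqRecord(ident, "bold", organism, gene, seq))
        report.n_parsed += 1
    return out, report


@dataclass(frozen=True)
class SearchTerm:
    """One repository query: taxon x gene synonyms x year window x origin."""

    taxon: str
    gene_synonyms: tuple[str, ...] = DEFAULT_GENE_SYNONYMS
    year_from: int = 2003
    year_to: int = 2019
    barcode_keyword: bool = False
    origin: str = "Eukaryota"

    def __post_init__(self):
        if not self.gene_synonyms:
            raise ValueError("gene_synonyms must be non-empty")
        if self.year_from > self.year_to:
            raise ValueError("year_from must not exceed year_to")


def build_search_terms(
    taxa: list[str],
    gene_synonyms: tuple[str, ...] = DEFAULT_GENE_SYNONYMS,
    year_from: int = 2003,
    year_to: int = 2019,
    barcode_keyword: bool = False,
    origin: str = "Eukaryota",
) -> list[SearchTerm]:
    """One :class:`SearchTerm` per taxon with shared retrieval settings."""
    if not taxa:
        raise ValueError("taxa list must be non-empty")
    return [
        SearchTerm(t, tuple(gene_synonyms), year_from, year_to, barcode_keyword, origin)
        for t in taxa
    ]


def render_entrez_query(term: SearchTerm) -> str:
    """Serialize a term to an Entrez-style query string."""
    genes = " OR ".join(f"{g}[All Fields]" for g in term.gene_synonyms)
    parts = [
        f'"{term.taxon}"[Organism]',
        f"({genes})",
        f'("{term.year_from}"[PDAT] : "{term.year_to}"[PDAT])',
        f"{term.origin}[Organism]",
    ]
    if term.barcode_keyword:
        parts.append("barcode[All Fields]")
    return " AND ".join(parts)
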