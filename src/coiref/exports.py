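"""Export the normalized database in Kraken2-, MEGAN- and BLAST-ready forms.

The package emits the *inputs* these tools consume (FASTA dialects and
accession→TaxID maps); invoking kraken2-build / makeblastdb themselves is an
optional shell-out left to the user.  Every exported sequence carries exactly
one TaxID annotation; exports are lossless for (accession, tax_id, sequence).
"""

from __future__ import annotations

from .errors import ExportError
from .records import ReferenceDatabase, SeqRecord

#: conventional FASTA line width; fixed for bit-stable output.
FASTA_WRAP = 80


def _wrap(seq: str, width: int = FASTA_WRAP) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _require_taxid(rec: SeqRecord) -> int:
    if rec.tax_id is None:
        raise ExportError(f"record {rec.accession} has no TaxID; normalize first")
    return rec.tax_id


def _require_unique_accessions(db: ReferenceDatabase) -> None:
    seen: set[str] = set()
    for rec in db.records:
        if rec.accession in seen:
            raise ExportError(
                f"duplicate accession {rec.accession}; disambiguate before export"
            )
        seen.add(rec.accession)


def normalized_header(rec: SeqRecord) -> str:
    """Normalized-FASTA header: accession, taxon label, TaxID, gene label."""
    label = rec.canonical_name or rec.organism_name
    return f">{rec.accession};taxlabel={label};taxid={_require_taxid(rec)};gene={rec.gene_label}"


def to_normalized_fasta(db: ReferenceDatabase) -> str:
    """FASTA with the documented normalized header layout."""
    chunks = [f"{normalized_header(r)}\n{_wrap(r.sequence)}" for r in db.records]
    return "\n".join(chunks) + ("\n" if chunks else "")


def to_kraken_fasta(db: ReferenceDatabase) -> str:
    """Kraken2 custom-database FASTA: ``>accession|kraken:taxid|TaxID``."""
    chunks = [
        f">{r.accession}|kraken:taxid|{_require_taxid(r)}\n{_wrap(r.sequence)}"
        for r in db.records
    ]
    return "\n".join(chunks) + ("\n" if chunks else "")


def to_megan_inputs(db: ReferenceDatabase) -> tuple[str, str]:
    """(normalized FASTA, accession→TaxID TSV) for MEGAN via a BLAST database."""
    _require_unique_accessions(db)
    fasta = to_normalized_fasta(db)
    rows = [f"{r.accession}\t{_require_taxid(r)}" for r in db.records]
    return fasta, "\n".join(rows) + ("\n" if rows else "")


def to_blast_inputs(db: ReferenceDatabase) -> tuple[str, str]:
    """(FASTA, taxid_map) pair following the makeblastdb -taxid_map dialect."""
    _require_unique_accessions(db)
    fasta = to_normalized_fasta(db)
    rows = [f"{r.accession} {_require_taxid(r)}" for r in db.records]
    return fasta, "\n".join(rows) + ("\n" if rows else "")
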