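"""Plain-text interchange of record sets between CLI stages.

A record table is TSV with one row per sequence; it round-trips everything a
:class:`~coiref.records.SeqRecord` carries, including normalization results
and screening flags, so any pipeline stage can be run stand-alone.
"""

from __future__ import annotations

import csv
import io

from .records import ReferenceDatabase, SeqRecord

COLUMNS = (
    "accession", "source", "organism_name", "gene_label", "sequence",
    "tax_id", "canonical_name", "name_level", "flags",
)


def records_to_tsv(records: list[SeqRecord]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    for r in records:
        writer.writerow([
            r.accession, r.source, r.organism_name, r.gene_label, r.sequence,
            "" if r.tax_id is None else r.tax_id,
            r.canonical_name or "", r.name_level or "",
            ";".join(sorted(r.flags)),
        ])
    return buf.getvalue()


def records_from_tsv(text: str) -> list[SeqRecord]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    out = []
    for row in reader:
        out.append(
            SeqRecord(
                accession=row["accession"],
                source=row["source"],
                organism_name=row["organism_name"],
                gene_label=row["gene_label"],
                sequence=row["sequence"],
                tax_id=int(row["tax_id"]) if row.get("tax_id") else None,
                canonical_name=row.get("canonical_name") or None,
                name_level=row.get("name_level") or None,
                flags=set(filter(None, (row.get("flags") or "").split(";"))),
            )
        )
    return out


def database_to_tsv(db: ReferenceDatabase) -> str:
    return records_to_tsv(db.records)


def database_from_tsv(text: str) -> ReferenceDatabase:
    return ReferenceDatabase(records=records_from_tsv(text))
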