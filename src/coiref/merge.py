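"""Blacklist filtering, merging of repository record sets, dereplication.

Dereplication collapses exact full-length duplicates (case-insensitive string
equality after canonicalization), keeping the first record in merged order —
GenBank-derived before BOLD-derived, each in input order.  This mirrors
vsearch-style full-length dereplication; reverse complements are NOT treated
as duplicates, and no similarity clustering is done.
"""

from __future__ import annotations

from .records import ReferenceDatabase, SeqRecord


def parse_blacklist(text: str) -> list[str]:
    """One accession per line; '#' starts a comment; blanks ignored."""
    out = []
    for line in text.splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def _strip_version(accession: str) -> str:
    return accession.rsplit(".", 1)[0]


def filter_blacklist(
    records: list[SeqRecord], blacklisted_accessions: list[str]
) -> tuple[list[SeqRecord], int, list[str]]:
    """Drop records whose accession (full or version-stripped) is blacklisted.

    Returns ``(kept, removed_count, unused_entries)``; blacklist entries that
    matched nothing are reported, not errors.
    """
    bl = set(blacklisted_accessions)
    kept, used = [], set()
    for rec in records:
        hit = {rec.accession, _strip_version(rec.accession)} & bl
        if hit:
            used |= hit
        else:
            kept.append(rec)
    unused = sorted(bl - used)
    return kept, len(records) - len(kept), unused


def merge(
    db_a: list[SeqRecord],
    db_b: list[SeqRecord],
    provenance_a: str = "genbank",
    provenance_b: str = "bold",
) -> ReferenceDatabase:
    """Concatenate two record sets (a then b), no dereplication yet.

    Accession collisions across the two inputs are kept (identical sequences
    are resolved later by dereplication) but reported in the derivation log.
    """
    records = list(db_a) + list(db_b)
    db = ReferenceDatabase(records=records)
    db.provenance = {
        provenance_a: len(db_a),
        provenance_b: len(db_b),
    }
    collisions = sorted(
        {r.accession for r in db_a} & {r.accession for r in db_b}
    )
    db.log_step(
        "merge",
        n_in=len(db_a) + len(db_b),
        n_out=len(records),
        accession_collisions=collisions,
    )
    return db


def dereplicate(db: ReferenceDatabase) -> ReferenceDatabase:
    """Collapse exact full-length duplicate sequences to the first-seen record.

    The cluster map (kept accession -> collapsed accessions) and any organism
    name conflicts among collapsed records are kept in the derivation log.
    Idempotent.
    """
    seen: dict[str, SeqRecord] = {}
    clusters: dict[str, list[str]] = {}
    name_conflicts: list[tuple[str, str, str]] = []
    kept: list[SeqRecord] = []
    for rec in db.records:
        key = rec.sequence.upper()
        head = seen.get(key)
        if head is None:
            seen[key] = rec
            kept.append(rec)
        else:
            clusters.setdefault(head.accession, []).append(rec.accession)
            if rec.organism_name != head.organism_name:
                name_conflicts.append(
                    (head.accession, head.organism_name, rec.organism_name)
                )
    out = ReferenceDatabase(
        records=kept,
        provenance=dict(db.provenance),
        derivation_log=list(db.derivation_log),
    )
    out.log_step(
        "dereplicate",
        n_in=len(db.records),
        n_out=len(kept),
        clusters=clusters,
        name_conflicts=name_conflicts,
    )
    return out
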