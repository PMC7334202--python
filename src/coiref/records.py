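"""Core record containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: IUPAC nucleotide one-letter codes accepted after cleaning.
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

#: characters silently stripped on ingest (alignment gaps, padding).
GAP_CHARACTERS = "-."


def clean_sequence(raw: str) -> tuple[str, bool]:
    """Canonicalize a nucleotide string: drop gaps/whitespace, uppercase.

    Returns ``(cleaned, ok)``; ``ok`` is False when a non-IUPAC letter
    remains, in which case the record should be skipped and reported.
    """
    cleaned = "".join(
        c for c in raw.upper() if c not in GAP_CHARACTERS and not c.isspace()
    )
    return cleaned, bool(cleaned) and set(cleaned) <= IUPAC_NUCLEOTIDES


@dataclass
class SeqRecord:
    """One reference sequence with its repository metadata.

    ``tax_id``, ``canonical_name`` and ``name_level`` stay unset until the
    normalization stage attaches them.  ``flags`` collects screening marks
    such as ``marine``, ``contaminant`` or ``ambiguous_homonym``.
    """

    accession: str
    source: str  # "genbank" | "bold"
    organism_name: str
    gene_label: str
    sequence: str
    tax_id: Optional[int] = None
    canonical_name: Optional[str] = None
    name_level: Optional[str] = None  # "species" | "genus" | "unusable"
    flags: set[str] = field(default_factory=set)


@dataclass
class ReferenceDatabase:
    """Ordered collection of records with provenance and a derivation log.

    Each pipeline step appends a log entry carrying its before/after counts,
    so the full derivation of the final database is machine-auditable.
    """

    records: list[SeqRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    derivation_log: list[dict] = field(default_factory=list)

    def log_step(self, step: str, n_in: int, n_out: int, **details) -> None:
        self.derivation_log.append(
            {"step": step, "n_in": n_in, "n_out": n_out, **details}
        )

    def __len__(self) -> int:
        return len(self.records)
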