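"""Checklist screening: marine membership and contaminant handling.

Checklists are name-based (family and/or species rank) rather than
TaxID-based because the marine register (WoRMS-style) and the NCBI taxonomy
are distinct nomenclatures; matching is case-insensitive.  A record is marine
when its species binomial appears in the checklist species set OR its lineage
passes through a checklist family — families with marine members are included
wholesale, so terrestrial relatives inside marine families are kept and remain
assignable at genus/family level.  Marine and contaminant flags are
independent; screening never alters sequences or TaxIDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ReferenceDatabase, SeqRecord
from .taxonomy import TaxonomyIndex, normalize_name


@dataclass
class Checklist:
    """Named set of family- and/or species-level taxa."""

    name: str
    families: set[str] = field(default_factory=set)
    species: set[str] = field(default_factory=set)

    def __post_init__(self):
        self._families_key = {normalize_name(f) for f in self.families}
        self._species_key = {normalize_name(s) for s in self.species}

    @property
    def level(self) -> str:
        if self.families and self.species:
            return "mixed"
        return "family" if self.families else "species"


def parse_checklist_tsv(text: str, name: str = "checklist") -> Checklist:
    """Checklist TSV: columns ``name<TAB>rank`` with rank in {family, species}.

    A header line naming the columns is permitted and skipped.
    """
    families: set[str] = set()
    species: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if lineno == 1 and [p.lower() for p in parts[:2]] == ["name", "rank"]:
            continue
        if len(parts) < 2:
            raise ValueError(f"checklist line {lineno}: expected name<TAB>rank")
        taxon, rank = parts[0].strip(), parts[1].strip().lower()
        if rank == "family":
            families.add(taxon)
        elif rank == "species":
            species.add(taxon)
        else:
            raise ValueError(f"checklist line {lineno}: unknown rank '{rank}'")
    return Checklist(name, families, species)


def _record_family(rec: SeqRecord, index: TaxonomyIndex | None) -> str | None:
    if index is None or rec.tax_id is None or rec.tax_id not in index.nodes:
        return None
    for rank, name, _ in index.lineage(rec.tax_id):
        if rank == "family":
            return name
    return None


def _matches(
    rec: SeqRecord, checklist: Checklist, index: TaxonomyIndex | None
) -> tuple[bool, bool]:
    """(hit, family_known) for one record against a checklist."""
    family = _record_family(rec, index)
    if (
        rec.name_level == "species"
        and rec.canonical_name
        and normalize_name(rec.canonical_name) in checklist._species_key
    ):
        return True, family is not None
    if family is not None:
        return normalize_name(family) in checklist._families_key, True
    return False, False


def screen_marine(
    db: ReferenceDatabase, checklist: Checklist, index: TaxonomyIndex
) -> tuple[ReferenceDatabase, dict]:
    """Flag marine records in place; return the db and summary counts.

    Summary: flagged record count, unique flagged species binomials (the
    marine species count used by composition statistics), and the number of
    records whose lineage lacks a family rank (evaluated on the species set
    only).
    """
    n_flagged = 0
    n_no_family = 0
    marine_species: set[str] = set()
    for rec in db.records:
        hit, family_known = _matches(rec, checklist, index)
        if not family_known:
            n_no_family += 1
        if hit:
            rec.flags.add("marine")
            n_flagged += 1
            if rec.name_level == "species" and rec.canonical_name:
                marine_species.add(normalize_name(rec.canonical_name))
    summary = {
        "n_marine_records": n_flagged,
        "n_marine_species": len(marine_species),
        "n_no_family_rank": n_no_family,
    }
    db.log_step("screen_marine", n_in=len(db.records), n_out=len(db.records), **summary)
    return db, summary


CONTAMINANT_POLICIES = ("flag", "remove", "merge")


def screen_contaminants(
    db: ReferenceDatabase,
    contaminant_list: Checklist,
    policy: str = "flag",
    index: TaxonomyIndex | None = None,
) -> tuple[ReferenceDatabase, dict]:
    """Flag, remove, or merge-with-flag contaminant records.

    ``flag`` only marks records; ``remove`` drops them from the output (the
    removed records plus the output partition the input); ``merge`` keeps the
    contaminant records in the main database with their flag retained.
    The report lists hit counts per contaminant taxon.  An index is only
    needed when the contaminant list has family-level entries.
    """
    if policy not in CONTAMINANT_POLICIES:
        raise ValueError(f"unknown contaminant policy '{policy}'")
    per_taxon: dict[str, int] = {}
    flagged: list[SeqRecord] = []
    kept: list[SeqRecord] = []
    for rec in db.records:
        hit, _ = _matches(rec, contaminant_list, index)
        if hit:
            rec.flags.add("contaminant")
            flagged.append(rec)
            key = rec.canonical_name or rec.organism_name
            per_taxon[key] = per_taxon.get(key, 0) + 1
        if not (hit and policy == "remove"):
            kept.append(rec)
    out = ReferenceDatabase(
        records=kept,
        provenance=dict(db.provenance),
        derivation_log=list(db.derivation_log),
    )
    report = {
        "policy": policy,
        "n_contaminant_records": len(flagged),
        "per_taxon": per_taxon,
        "removed": [r.accession for r in flagged] if policy == "remove" else [],
    }
    out.log_step(
        "screen_contaminants", n_in=len(db.records), n_out=len(kept), **report
    )
    return out, report
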