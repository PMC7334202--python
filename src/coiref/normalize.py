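"""Taxonomic normalization: attach a TaxID to every record or drop it.

The resolution cascade per record:

1. resolve the canonical name (scientific names first, then synonym-type
   classes), so synonymous species retain the correct TaxID;
2. if unresolved and the name is a species-level binomial, resolve the genus;
   when the genus is known, mint a new species TaxID nested within it
   (one greater than the current maximum TaxID of the local taxonomy);
3. otherwise the record is removed from the database.

Genus-level names (e.g. "Abra sp.") that resolve to a genus TaxID get the
genus TaxID directly — no new node is needed.  Names sharing one unresolvable
species binomial trigger exactly one mint, reused for every record carrying
the name.  Taxa without usable genus information cannot be rescued; their
records are dropped and enumerated in the report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records import ReferenceDatabase, SeqRecord
from .taxonomy import TaxonomyIndex

#: identification qualifiers trimmed from organism names before binomial
#: extraction ("Abra sp. NZ-2019", "Abra cf. alba", ...).
QUALIFIER_TOKENS = frozenset(
    {"sp", "spp", "cf", "aff", "nr", "gen", "indet", "complex", "group"}
)

_GENUS_RE = re.compile(r"^[A-Z][a-z]+$")
_EPITHET_RE = re.compile(r"^[a-z][a-z-]+$")


def extract_binomial(organism_name: str) -> tuple[str, str]:
    """Reduce an organism name to ``(canonical_name, level)``.

    ``level`` is ``species`` (clean binomial; trinomials are truncated),
    ``genus`` (genus name alone or followed only by qualifiers/voucher
    codes), or ``unusable``.  Quoted epithets and qualifier tokens are
    discarded before classification.
    """
    tokens = []
    for tok in organism_name.split():
        if any(q in tok for q in "'\"“”"):
            continue
        if tok.rstrip(".").lower() in QUALIFIER_TOKENS:
            continue
        tokens.append(tok)
    if not tokens or not _GENUS_RE.match(tokens[0]):
        return organism_name.strip(), "unusable"
    genus = tokens[0]
    if len(tokens) >= 2 and _EPITHET_RE.match(tokens[1]):
        return f"{genus} {tokens[1]}", "species"
    return genus, "genus"


@dataclass
class NormalizationReport:
    """Partition of the input records by resolution outcome."""

    n_exact: int = 0
    n_synonym: int = 0
    n_minted: int = 0
    n_dropped: int = 0
    dropped_names: list[str] = field(default_factory=list)
    minted_pairs: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_exact + self.n_synonym + self.n_minted + self.n_dropped


def normalize_records(
    db: ReferenceDatabase, index: TaxonomyIndex
) -> tuple[ReferenceDatabase, NormalizationReport]:
    """Attach TaxIDs via the resolution cascade; drop unresolvable records.

    Canonical names are deduplicated and processed in first-occurrence order,
    so replaying on identical inputs against a fresh copy of the same
    taxonomy yields identical minted IDs.  The index is mutated in place
    (minted nodes are appended).
    """
    # first pass: one decision per distinct canonical name
    decisions: dict[tuple[str, str], tuple] = {}
    canon: list[tuple[str, str]] = []
    for rec in db.records:
        canon.append(extract_binomial(rec.organism_name))
    for name, level in canon:
        key = (name, level)
        if key in decisions or level == "unusable":
            continue
        res = index.resolve_name(name)
        if res.tax_id is not None:
            decisions[key] = (res.tax_id, res.match_class, res.ambiguous)
            continue
        if level == "species":
            genus = name.split()[0]
            gres = index.resolve_name(genus)
            if gres.tax_id is not None:
                minted = index.mint_taxid(name, gres.tax_id)
                decisions[key] = (minted, "genus_fallback_minted", gres.ambiguous)
                continue
        decisions[key] = (None, "unresolved", False)

    report = NormalizationReport()
    kept: list[SeqRecord] = []
    minted_seen: set[str] = set()
    for rec, (name, level) in zip(db.records, canon):
        decision = decisions.get((name, level), (None, "unresolved", False))
        tax_id, match_class, ambiguous = decision
        if tax_id is None:
            report.n_dropped += 1
            report.dropped_names.append(rec.organism_name)
            continue
        rec.tax_id = tax_id
        rec.canonical_name = name
        rec.name_level = level
        if ambiguous:
            rec.flags.add("ambiguous_homonym")
        if match_class == "exact_scientific":
            report.n_exact += 1
        elif match_class == "synonym":
            report.n_synonym += 1
        else:
            report.n_minted += 1
            if name not in minted_seen:
                minted_seen.add(name)
                report.minted_pairs.append((name, tax_id))
        kept.append(rec)

    out = ReferenceDatabase(
        records=kept,
        provenance=dict(db.provenance),
        derivation_log=list(db.derivation_log),
    )
    out.log_step(
        "normalize",
        n_in=len(db.records),
        n_out=len(kept),
        n_exact=report.n_exact,
        n_synonym=report.n_synonym,
        n_minted=report.n_minted,
        n_dropped=report.n_dropped,
        minted_pairs=list(report.minted_pairs),
    )
    return out, report


def report_to_tsv(report: NormalizationReport) -> str:
    """Serialize a normalization report as TSV (key/value plus detail rows)."""
    lines = [
        "key\tvalue",
        f"n_exact\t{report.n_exact}",
        f"n_synonym\t{report.n_synonym}",
        f"n_minted\t{report.n_minted}",
        f"n_dropped\t{report.n_dropped}",
    ]
    for name, tid in report.minted_pairs:
        lines.append(f"minted\t{name}\t{tid}")
    for name in report.dropped_names:
        lines.append(f"dropped\t{name}")
    return "\n".join(lines) + "\n"
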