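"""Deterministic miniature fixtures: taxonomies, repository files, checklists.

The generator emulates the *shape* of the real inputs — an NCBI-style
taxdump, a GenBank flatfile, a BOLD-style TSV, blacklists and marine /
contaminant checklists — at desk scale, with every curation branch planted on
purpose: exact duplicates (copied, not left to chance), synonym-named
records, novel species requiring a minted TaxID, unresolvable records that
must be dropped, blacklisted accessions, genus-only BOLD rows and empty
nucleotide rows.  Every planted fact is recorded in a truth table so an
end-to-end pipeline run can be checked exactly.

Sequences are uniform random DNA (default 120 bp) with uniqueness enforced,
so the only identical sequences are the planted duplicates.  One global seed
drives everything; per-section generators are seeded as ``"{seed}-tree"``,
``"{seed}-repo"`` and ``"{seed}-checklist}"`` so each artifact is
independently reproducible.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field, asdict
from functools import lru_cache

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio import SeqIO

from .screen import Checklist
from .taxonomy import (
    NameRecord,
    TaxonomyIndex,
    TaxonomyNode,
    write_taxonomy_dump,
)

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni",
    "po", "ra", "su", "ti", "vo", "xa", "ze", "ky",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and planted-event rates of one synthetic study.

    Fractions apply to base record counts (duplicate, blacklist) or to the
    species count (novel, dropped); ``synonym_fraction`` is the fraction of
    species carrying a synonym name — all records of such a species use the
    synonym, so the record-level synonym rate matches.
    """

    seed: int = 0
    n_families: int = 3
    n_genera_per_family: int = 2
    n_species_per_genus: int = 3
    overlap_fraction: float = 0.5
    duplicate_fraction: float = 0.15
    synonym_fraction: float = 0.2
    novel_species_fraction: float = 0.15
    dropped_fraction: float = 0.1
    blacklist_fraction: float = 0.05
    marine_family_fraction: float = 0.6
    n_marine_species_entries: int = 1
    contaminant_names: tuple[str, ...] = ("Homo sapiens",)
    n_genus_only_bold: int = 1
    n_empty_nucleotide_rows: int = 1
    seq_length: int = 120

    def __post_init__(self):
        for name in (
            "overlap_fraction", "duplicate_fraction", "synonym_fraction",
            "novel_species_fraction", "dropped_fraction", "blacklist_fraction",
            "marine_family_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_families", "n_genera_per_family", "n_species_per_genus",
                     "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FixtureTruth:
    """Every planted fact, for exact assertion after a pipeline run."""

    n_genbank_records: int = 0
    n_bold_rows: int = 0
    n_bold_parsed: int = 0
    n_bold_skipped: int = 0
    n_blacklisted_removed: int = 0
    n_unused_blacklist_entries: int = 0
    n_merged: int = 0
    n_duplicates_collapsed: int = 0
    n_after_derep: int = 0
    n_exact: int = 0
    n_synonym: int = 0
    n_minted_records: int = 0
    n_expected_mints: int = 0
    minted_pairs: list[tuple[str, int]] = field(default_factory=list)
    n_dropped: int = 0
    n_after_normalize: int = 0
    n_marine_records: int = 0
    n_marine_species: int = 0
    n_contaminant_records: int = 0
    n_after_contaminant_removal: int = 0
    n_unique_species_final: int = 0
    species_set_genbank: set[str] = field(default_factory=set)
    species_set_bold: set[str] = field(default_factory=set)
    species_set_final: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return asdict(self)

    def to_tsv(self) -> str:
        rows = ["key\tvalue"]
        for key, val in self.as_dict().items():
            if isinstance(val, (set, frozenset)):
                val = ";".join(sorted(val))
            elif isinstance(val, list):
                val = ";".join(f"{n}={t}" for n, t in val)
            rows.append(f"{key}\t{val}")
        return "\n".join(rows) + "\n"


@dataclass
class Fixture:
    """A complete generated input set plus its ground truth."""

    spec: FixtureSpec
    names_text: str
    nodes_text: str
    genbank_text: str
    bold_tsv: str
    blacklist_text: str
    marine_checklist: Checklist
    contaminant_checklist: Checklist
    truth: FixtureTruth


# -- internal planning -------------------------------------------------------


@dataclass
class _Species:
    tax_id: int
    name: str
    genus: str
    family: str
    synonym: str | None
    contaminant: bool

    @property
    def visible_name(self) -> str:
        return self.synonym or self.name


@dataclass
class _PlannedRecord:
    repo: str  # "genbank" | "bold"
    accession: str
    organism: str
    sequence: str  # canonical (cleaned) form
    fate: str  # exact | synonym | minted | dropped | blacklisted | duplicate
    family: str | None = None
    level: str = "species"
    genus_name: str | None = None  # for BOLD genus-only rows


class _NamePool:
    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int, suffix: str = "") -> str:
        while True:
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables)) + suffix
            if w not in self.used:
                self.used.add(w)
                return w


def _build_tree(spec: FixtureSpec) -> tuple[TaxonomyIndex, list[_Species], list[str]]:
    """Construct the taxonomy index plus structured species/genus listings."""
    rng = random.Random(f"{spec.seed}-tree")
    pool = _NamePool(rng)
    index = TaxonomyIndex()

    def add(tax_id: int, parent: int, rank: str, name: str,
            synonym: str | None = None) -> None:
        index._add_node(TaxonomyNode(tax_id, parent, rank))
        index._add_name(NameRecord(tax_id, name, "scientific name"))
        if synonym:
            index._add_name(NameRecord(tax_id, synonym, "synonym"))

    add(1, 1, "no rank", "root")
    add(2, 1, "kingdom", "Eukaryota")
    next_id = 3
    species: list[_Species] = []
    genera: list[str] = []
    for _ in range(spec.n_families):
        family = pool.word(2, "idae").capitalize()
        family_id = next_id
        next_id += 1
        add(family_id, 2, "family", family)
        for _ in range(spec.n_genera_per_family):
            genus = pool.word(3).capitalize()
            genus_id = next_id
            next_id += 1
            add(genus_id, family_id, "genus", genus)
            genera.append(genus)
            for _ in range(spec.n_species_per_genus):
                epithet = pool.word(3)
                name = f"{genus} {epithet}"
                synonym = (
                    f"{genus} {epithet}ensis"
                    if rng.random() < spec.synonym_fraction
                    else None
                )
                add(next_id, genus_id, "species", name, synonym)
                species.append(
                    _Species(next_id, name, genus, family, synonym, False)
                )
                next_id += 1
    for contaminant in spec.contaminant_names:
        parts = contaminant.split()
        genus = parts[0]
        family = f"{genus}idae"
        family_id, genus_id, sp_id = next_id, next_id + 1, next_id + 2
        next_id += 3
        add(family_id, 2, "family", family)
        add(genus_id, family_id, "genus", genus)
        add(sp_id, genus_id, "species", contaminant)
        species.append(_Species(sp_id, contaminant, genus, family, None, True))
    return index, species, genera


def _random_seq(rng: random.Random, length: int, used: set[str]) -> str:
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        if seq not in used:
            used.add(seq)
            return seq


def _marine_selection(
    spec: FixtureSpec, species: list[_Species]
) -> tuple[set[str], set[str]]:
    """(marine families, species-level checklist entries), seed-stable."""
    rng = random.Random(f"{spec.seed}-checklist")
    families = sorted({s.family for s in species if not s.contaminant})
    k = round(spec.marine_family_fraction * len(families))
    marine_families = set(rng.sample(families, k)) if k else set()
    candidates = sorted(
        s.visible_name
        for s in species
        if not s.contaminant and s.family not in marine_families and s.synonym is None
    )
    n_entries = min(spec.n_marine_species_entries, len(candidates))
    marine_species = set(rng.sample(candidates, n_entries)) if n_entries else set()
    return marine_families, marine_species


@lru_cache(maxsize=32)
def _plan(spec: FixtureSpec) -> tuple:
    """Plan every record and compute the truth table.  Pure in the spec."""
    index, species, genera = _build_tree(spec)
    rng = random.Random(f"{spec.seed}-repo")
    seqs: set[str] = set()
    pool = _NamePool(random.Random(f"{spec.seed}-names"))
    max_tax_id = index.max_tax_id

    base_species = [s for s in species if not s.contaminant]
    n = len(base_species)
    n_overlap = round(spec.overlap_fraction * n)
    in_both = set(
        s.tax_id for s in rng.sample(base_species, min(n_overlap, n))
    )
    gb_records: list[_PlannedRecord] = []
    bold_records: list[_PlannedRecord] = []
    side = 0
    for sp in base_species:
        fate = "synonym" if sp.synonym else "exact"
        repos = ["genbank", "bold"] if sp.tax_id in in_both else (
            ["genbank"] if side == 0 else ["bold"]
        )
        if sp.tax_id not in in_both:
            side ^= 1
        for repo in repos:
            rec = _PlannedRecord(
                repo, "", sp.visible_name,
                _random_seq(rng, spec.seq_length, seqs), fate, sp.family,
            )
            (gb_records if repo == "genbank" else bold_records).append(rec)
    base_records = gb_records + bold_records
    n_base = len(base_records)

    # blacklist extras: valid records of existing species, removed pre-merge
    blacklist_extras: list[_PlannedRecord] = []
    n_bl = round(spec.blacklist_fraction * n_base)
    for i in range(n_bl):
        sp = rng.choice(base_species)
        repo = "genbank" if i % 2 == 0 else "bold"
        blacklist_extras.append(
            _PlannedRecord(
                repo, "", sp.visible_name,
                _random_seq(rng, spec.seq_length, seqs), "blacklisted", sp.family,
            )
        )

    # exact duplicates: copy of a base record's sequence, same repository,
    # placed after the source so the source is kept
    n_dup = min(round(spec.duplicate_fraction * n_base), n_base)
    dup_extras = [
        _PlannedRecord(src.repo, "", src.organism, src.sequence,
                       "duplicate", src.family)
        for src in rng.sample(base_records, n_dup)
    ]

    # novel species: known genus, epithet absent from the taxonomy -> mint
    n_novel = round(spec.novel_species_fraction * n)
    novel_extras: list[_PlannedRecord] = []
    for i in range(n_novel):
        genus = rng.choice(genera)
        name = f"{genus} {pool.word(3, 'oides')}"
        family = next(s.family for s in base_species if s.genus == genus)
        novel_extras.append(
            _PlannedRecord(
                "genbank" if i % 2 == 0 else "bold", "", name,
                _random_seq(rng, spec.seq_length, seqs), "minted", family,
            )
        )

    # unresolvable records -> dropped at normalization
    n_drop = round(spec.dropped_fraction * n)
    drop_extras: list[_PlannedRecord] = []
    for i in range(n_drop):
        kind = i % 3
        # "Qz" prefix keeps these genera disjoint from every generated genus
        if kind == 0:
            name = f"Qz{pool.word(2)} sp."  # unknown genus, genus-level
        elif kind == 1:
            name = f"Qz{pool.word(2)} {pool.word(3)}"  # unknown genus, species-level
        else:
            name = f"environmental sample {i}"  # unusable
        drop_extras.append(
            _PlannedRecord(
                "genbank" if i % 2 == 0 else "bold", "", name,
                _random_seq(rng, spec.seq_length, seqs), "dropped", None,
            )
        )

    contaminant_records = [
        _PlannedRecord(
            "genbank", "", sp.name,
            _random_seq(rng, spec.seq_length, seqs), "exact", sp.family,
        )
        for sp in species
        if sp.contaminant
    ]

    genus_only_rows = []
    for i in range(spec.n_genus_only_bold):
        genus = rng.choice(genera)
        family = next(s.family for s in base_species if s.genus == genus)
        genus_only_rows.append(
            _PlannedRecord("bold", "", "", _random_seq(rng, spec.seq_length, seqs),
                           "exact", family, level="genus", genus_name=genus)
        )

    # assemble per-repository ordered record lists and assign accessions
    gb_all = (
        list(gb_records)
        + [r for r in blacklist_extras if r.repo == "genbank"]
        + [r for r in dup_extras if r.repo == "genbank"]
        + [r for r in novel_extras if r.repo == "genbank"]
        + [r for r in drop_extras if r.repo == "genbank"]
        + contaminant_records
    )
    bold_all = (
        [r for r in bold_records]
        + [r for r in blacklist_extras if r.repo == "bold"]
        + [r for r in dup_extras if r.repo == "bold"]
        + [r for r in novel_extras if r.repo == "bold"]
        + [r for r in drop_extras if r.repo == "bold"]
        + genus_only_rows
    )
    for i, rec in enumerate(gb_all, start=1):
        rec.accession = f"SIM{i:06d}.1"
    for i, rec in enumerate(bold_all, start=1):
        rec.accession = f"FIXT{i:05d}"

    blacklist_entries = [r.accession for r in blacklist_extras] + ["UNUSED0000"]

    marine_families, marine_species_entries = _marine_selection(spec, species)

    # ---- truth ----
    truth = FixtureTruth()
    truth.n_genbank_records = len(gb_all)
    truth.n_bold_rows = len(bold_all) + spec.n_empty_nucleotide_rows
    truth.n_bold_parsed = len(bold_all)
    truth.n_bold_skipped = spec.n_empty_nucleotide_rows
    truth.n_blacklisted_removed = len(blacklist_extras)
    truth.n_unused_blacklist_entries = 1
    truth.n_merged = len(gb_all) + len(bold_all) - len(blacklist_extras)
    truth.n_duplicates_collapsed = len(dup_extras)
    truth.n_after_derep = truth.n_merged - truth.n_duplicates_collapsed

    surviving = (
        [r for r in gb_all + bold_all if r.fate in ("exact", "synonym", "minted")]
    )
    truth.n_exact = sum(1 for r in surviving if r.fate == "exact")
    truth.n_synonym = sum(1 for r in surviving if r.fate == "synonym")
    truth.n_minted_records = sum(1 for r in surviving if r.fate == "minted")
    truth.n_dropped = len(drop_extras)
    truth.n_after_normalize = len(surviving)
    truth.n_expected_mints = n_novel
    # mint order = first occurrence in merged (GenBank then BOLD) order
    merged_novel = [r for r in gb_all if r.fate == "minted"] + [
        r for r in bold_all if r.fate == "minted"
    ]
    truth.minted_pairs = [
        (r.organism, max_tax_id + 1 + i) for i, r in enumerate(merged_novel)
    ]

    def is_marine(rec: _PlannedRecord) -> bool:
        if rec.level == "species" and rec.organism in marine_species_entries:
            return True
        return rec.family in marine_families if rec.family else False

    marine_records = [r for r in surviving if is_marine(r)]
    truth.n_marine_records = len(marine_records)
    truth.n_marine_species = len(
        {r.organism.casefold() for r in marine_records if r.level == "species"}
    )
    truth.n_contaminant_records = len(contaminant_records)
    truth.n_after_contaminant_removal = (
        truth.n_after_normalize - truth.n_contaminant_records
    )
    contaminant_ids = {id(r) for r in contaminant_records}
    final = [r for r in surviving if id(r) not in contaminant_ids]
    truth.species_set_genbank = {
        r.organism for r in gb_all
        if r.fate in ("exact", "synonym", "minted") and r.level == "species"
    }
    truth.species_set_bold = {
        r.organism for r in bold_all
        if r.fate in ("exact", "synonym", "minted") and r.level == "species"
    }
    truth.species_set_final = {
        r.organism for r in final if r.level == "species"
    }
    truth.n_unique_species_final = len(
        {r.organism.casefold() for r in final if r.level == "species"}
    )

    checklists = (
        Checklist("marine", set(marine_families), set(marine_species_entries)),
        Checklist("contaminants", set(), set(spec.contaminant_names)),
    )
    return index, gb_all, bold_all, blacklist_entries, checklists, truth


# -- public surface ----------------------------------------------------------


def make_taxonomy(spec: FixtureSpec) -> tuple[str, str]:
    """(names_text, nodes_text) of the fixture taxonomy, reproducible from seed."""
    index, *_ = _plan(spec)
    return write_taxonomy_dump(index)


def _render_genbank(records: list[_PlannedRecord], gene_label: str = "COI") -> str:
    out = io.StringIO()
    bio_records = []
    for rec in records:
        br = BioSeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            name=rec.accession.rsplit(".", 1)[0],
            description=f"{rec.organism} cytochrome oxidase subunit 1 ({gene_label})",
        )
        br.annotations.update(
            molecule_type="DNA",
            organism=rec.organism,
            source=rec.organism,
            taxonomy=[],
        )
        bio_records.append(br)
    SeqIO.write(bio_records, out, "genbank")
    return out.getvalue()


def _render_bold(records: list[_PlannedRecord], spec: FixtureSpec,
                 gene_label: str = "COI-5P") -> str:
    rng = random.Random(f"{spec.seed}-bold-gaps")
    lines = ["processid\tspecies_name\tgenus_name\tmarkercode\tnucleotides"]
    for rec in records:
        # plant an alignment gap to exercise gap stripping on ingest
        seq = rec.sequence
        pos = rng.randrange(1, len(seq))
        gapped = seq[:pos] + "-" + seq[pos:]
        if rec.level == "genus":
            lines.append(f"{rec.accession}\t\t{rec.genus_name}\t{gene_label}\t{gapped}")
        else:
            genus = rec.organism.split()[0] if rec.organism else ""
            lines.append(
                f"{rec.accession}\t{rec.organism}\t{genus}\t{gene_label}\t{gapped}"
            )
    for i in range(spec.n_empty_nucleotide_rows):
        lines.append(f"EMPTY{i:04d}\tPlaceholder taxon\tPlaceholder\t{gene_label}\t")
    return "\n".join(lines) + "\n"


def make_repository_files(
    spec: FixtureSpec, taxonomy: tuple[str, str] | None = None
) -> tuple[str, str, FixtureTruth]:
    """(genbank_flatfile_text, bold_tsv_text, truth_table) for one spec.

    ``taxonomy`` is accepted for interface symmetry; generation is a pure
    function of the spec, so the texts always correspond to
    ``make_taxonomy(spec)``.
    """
    _, gb_all, bold_all, _, _, truth = _plan(spec)
    return _render_genbank(gb_all), _render_bold(bold_all, spec), truth


def make_checklists(
    spec: FixtureSpec, taxonomy: tuple[str, str] | None = None
) -> tuple[Checklist, Checklist]:
    """(marine_checklist, contaminant_checklist) consistent with the truth."""
    *_, checklists, _ = _plan(spec)
    return checklists


def make_blacklist(spec: FixtureSpec) -> str:
    """Blacklist text: planted accessions plus one deliberately unused entry."""
    _, _, _, entries, _, _ = _plan(spec)
    lines = ["# accessions excluded before merging"]
    lines += entries
    return "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the complete input set (all texts, checklists, truth)."""
    names_text, nodes_text = make_taxonomy(spec)
    gb_text, bold_text, truth = make_repository_files(spec)
    marine, contaminants = make_checklists(spec)
    return Fixture(
        spec=spec,
        names_text=names_text,
        nodes_text=nodes_text,
        genbank_text=gb_text,
        bold_tsv=bold_text,
        blacklist_text=make_blacklist(spec),
        marine_checklist=marine,
        contaminant_checklist=contaminants,
        truth=truth,
    )
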