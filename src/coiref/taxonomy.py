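"""NCBI-style taxonomy: taxdump parsing, name resolution, TaxID minting.

The taxonomy is held as a mutable local index over ``nodes.dmp`` /
``names.dmp`` content.  Reference databases built from multiple repositories
(GenBank, BOLD) must share one nomenclature, so every sequence is ultimately
keyed by an NCBI TaxID.  Species missing from the local taxonomy but with a
known genus receive a locally minted TaxID: one greater than the current
maximum, added as a species-rank node nested within the genus.  Minted IDs
therefore depend on the taxonomy version in use, and the extended taxonomy can
be written back out in taxdump dialect so downstream tools (Kraken2, MEGAN)
see a consistent tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import TaxdumpParseError, TaxonomyError

#: name classes consulted when a query is not an exact scientific name.
#: Mirrors GenBank TaxIdentifier behaviour; common names are deliberately
#: excluded to avoid silent misassignment.
SYNONYM_CLASSES = ("synonym", "equivalent name", "includes", "genbank synonym")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-insensitive key with internal whitespace collapsed."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class TaxonomyNode:
    tax_id: int
    parent_id: int  # self-referential at the root
    rank: str


@dataclass(frozen=True)
class NameRecord:
    tax_id: int
    name_txt: str
    name_class: str


@dataclass
class ResolutionResult:
    """Outcome of resolving one taxon name against the index.

    ``match_class`` is one of ``exact_scientific``, ``synonym``,
    ``genus_fallback_minted`` (set by the normalization cascade, never by
    :meth:`TaxonomyIndex.resolve_name` itself) or ``unresolved``.
    ``ambiguous`` marks homonyms: the name mapped to several TaxIDs and the
    homonym policy picked one.
    """

    query: str
    tax_id: Optional[int]
    match_class: str
    minted: bool = False
    ambiguous: bool = False


class TaxonomyIndex:
    """Mutable local copy of an NCBI-style taxonomy."""

    def __init__(self) -> None:
        self.nodes: dict[int, TaxonomyNode] = {}
        self.names: dict[str, list[NameRecord]] = {}
        self.scientific_name: dict[int, str] = {}
        self.max_tax_id: int = 0
        self.minted_ids: list[int] = []

    # -- construction -----------------------------------------------------

    def _add_node(self, node: TaxonomyNode) -> None:
        if node.tax_id in self.nodes:
            raise TaxdumpParseError(f"duplicate tax_id {node.tax_id} in nodes")
        self.nodes[node.tax_id] = node
        if node.tax_id > self.max_tax_id:
            self.max_tax_id = node.tax_id

    def _add_name(self, rec: NameRecord) -> None:
        if rec.name_class == "scientific name":
            if rec.tax_id in self.scientific_name:
                raise TaxdumpParseError(
                    f"tax_id {rec.tax_id} has more than one scientific name"
                )
            self.scientific_name[rec.tax_id] = rec.name_txt
        self.names.setdefault(normalize_name(rec.name_txt), []).append(rec)

    def _validate(self) -> None:
        for tax_id, node in self.nodes.items():
            if tax_id not in self.scientific_name:
                raise TaxdumpParseError(f"node {tax_id} lacks a scientific name")
            # walk to root; bounded by node count so cycles are caught
            seen = set()
            cur = node
            while cur.parent_id != cur.tax_id:
                if cur.tax_id in seen:
                    raise TaxdumpParseError(f"cycle in taxonomy at tax_id {cur.tax_id}")
                seen.add(cur.tax_id)
                parent = self.nodes.get(cur.parent_id)
                if parent is None:
                    raise TaxdumpParseError(
                        f"node {cur.tax_id} refers to missing parent {cur.parent_id}"
                    )
                cur = parent

    # -- queries ----------------------------------------------------------

    def root_id(self) -> int:
        for tax_id, node in self.nodes.items():
            if node.parent_id == tax_id:
                return tax_id
        raise TaxonomyError("taxonomy has no root node")

    def resolve_name(
        self, name: str, focal_tax_ids: Optional[set[int]] = None
    ) -> ResolutionResult:
        """Resolve a taxon name to a TaxID.

        Exact matches on the ``scientific name`` class win; otherwise the
        synonym-type classes are consulted.  Matching is case-insensitive with
        whitespace collapsed; no fuzzy matching.  Homonyms (one name, several
        TaxIDs) resolve to the TaxID whose lineage intersects
        ``focal_tax_ids`` if that is unique, else to the lowest TaxID; either
        way the result is flagged ``ambiguous``.
        """
        key = normalize_name(name)
        candidates = self.names.get(key, [])
        for classes, match_class in (
            (("scientific name",), "exact_scientific"),
            (SYNONYM_CLASSES, "synonym"),
        ):
            ids = sorted({r.tax_id for r in candidates if r.name_class in classes})
            if not ids:
                continue
            if len(ids) == 1:
                return ResolutionResult(name, ids[0], match_class)
            chosen = ids[0]
            if focal_tax_ids:
                in_focus = [
                    i
                    for i in ids
                    if focal_tax_ids.intersection(t for _, _, t in self.lineage(i))
                ]
                if len(in_focus) == 1:
                    chosen = in_focus[0]
            return ResolutionResult(name, chosen, match_class, ambiguous=True)
        return ResolutionResult(name, None, "unresolved")

    def lineage(self, tax_id: int) -> list[tuple[str, str, int]]:
        """(rank, scientific name, tax_id) from the query node up to the root."""
        if tax_id not in self.nodes:
            raise TaxonomyError(f"unknown tax_id {tax_id}")
        out = []
        cur = self.nodes[tax_id]
        while True:
            out.append((cur.rank, self.scientific_name[cur.tax_id], cur.tax_id))
            if cur.parent_id == cur.tax_id:
                return out
            cur = self.nodes[cur.parent_id]

    def mint_taxid(self, species_name: str, genus_tax_id: int) -> int:
        """Create a species-rank TaxID for ``species_name`` under a genus.

        The new ID is always ``max_tax_id + 1`` at call time, so replaying the
        same mint sequence on the same taxonomy version yields identical IDs.
        """
        if genus_tax_id not in self.nodes:
            raise TaxonomyError(f"cannot mint under unknown tax_id {genus_tax_id}")
        if self.resolve_name(species_name).tax_id is not None:
            raise TaxonomyError(
                f"'{species_name}' already resolves; resolve instead of minting"
            )
        new_id = self.max_tax_id + 1
        self._add_node(TaxonomyNode(new_id, genus_tax_id, "species"))
        self._add_name(NameRecord(new_id, species_name, "scientific name"))
        self.minted_ids.append(new_id)
        return new_id

    def expand_subtaxa(
        self, focal_names: Iterable[str], rank_filter: Optional[str] = None
    ) -> tuple[list[str], list[str]]:
        """Proper descendants of each focal taxon as scientific names.

        Returns ``(names, unresolved)``: names of all descendant nodes
        (optionally restricted to ``rank_filter``), deduplicated and ordered
        by ascending TaxID, plus the focal names that did not resolve.  The
        focal node itself is never included; add it explicitly if needed.
        """
        children: dict[int, list[int]] = {}
        for tax_id, node in self.nodes.items():
            if node.parent_id != tax_id:
                children.setdefault(node.parent_id, []).append(tax_id)

        unresolved: list[str] = []
        hits: set[int] = set()
        for name in focal_names:
            res = self.resolve_name(name)
            if res.tax_id is None:
                unresolved.append(name)
                continue
            stack = list(children.get(res.tax_id, []))
            while stack:
                tid = stack.pop()
                hits.add(tid)
                stack.extend(children.get(tid, []))
        if rank_filter is not None:
            hits = {t for t in hits if self.nodes[t].rank == rank_filter}
        return [self.scientific_name[t] for t in sorted(hits)], unresolved


# -- taxdump round trip ----------------------------------------------------

def _split_dmp_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_taxonomy_dump(names_text: str, nodes_text: str) -> TaxonomyIndex:
    """Parse names.dmp / nodes.dmp texts (NCBI taxdump dialect).

    Only tax_id, parent and rank (nodes) and tax_id, name_txt, name_class
    (names) are interpreted; other columns are ignored.  Raises
    :class:`TaxdumpParseError` on wrong field counts (with line number),
    duplicate node TaxIDs, missing scientific names, missing parents or
    cycles.
    """
    index = TaxonomyIndex()
    for lineno, line in enumerate(nodes_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 3:
            raise TaxdumpParseError(
                f"nodes.dmp line {lineno}: expected >=3 fields, got {len(fields)}"
            )
        try:
            tax_id, parent_id = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxdumpParseError(f"nodes.dmp line {lineno}: {exc}") from None
        index._add_node(TaxonomyNode(tax_id, parent_id, fields[2].strip()))
    for lineno, line in enumerate(names_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 4:
            raise TaxdumpParseError(
                f"names.dmp line {lineno}: expected >=4 fields, got {len(fields)}"
            )
        try:
            tax_id = int(fields[0])
        except ValueError as exc:
            raise TaxdumpParseError(f"names.dmp line {lineno}: {exc}") from None
        name_txt = fields[1].strip()
        if not name_txt:
            raise TaxdumpParseError(f"names.dmp line {lineno}: empty name_txt")
        index._add_name(NameRecord(tax_id, name_txt, fields[3].strip()))
    index._validate()
    return index


#: trailing empty columns of a 13-field nodes.dmp record (cols 4-13).
_NODES_TAIL = [""] * 10


def write_taxonomy_dump(index: TaxonomyIndex) -> tuple[str, str]:
    """Emit (names_text, nodes_text) in taxdump dialect.

    Nodes are sorted by TaxID; minted nodes are included, so the extended
    taxonomy can feed kraken2-build.  ``parse_taxonomy_dump`` of the output
    reproduces the node set, name set and max TaxID.
    """
    nodes_lines = []
    for tax_id in sorted(index.nodes):
        node = index.nodes[tax_id]
        fields = [str(node.tax_id), str(node.parent_id), node.rank, *_NODES_TAIL]
        nodes_lines.append("\t|\t".join(fields) + "\t|")
    name_recs = sorted(
        (rec for recs in index.names.values() for rec in recs),
        key=lambda r: (r.tax_id, r.name_class != "scientific name", r.name_txt),
    )
    names_lines = [
        "\t|\t".join([str(r.tax_id), r.name_txt, "", r.name_class]) + "\t|"
        for r in name_recs
    ]
    return "\n".join(names_lines) + "\n", "\n".join(nodes_lines) + "\n"
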