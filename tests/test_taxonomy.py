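"""Taxonomy index: taxdump parsing, resolution, minting, round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from coiref import (
    FixtureSpec,
    make_taxonomy,
    parse_taxonomy_dump,
    write_taxonomy_dump,
)
from coiref.errors import TaxdumpParseError, TaxonomyError

from conftest import NAMES_TEXT, NODES_TEXT, _dmp


class TestParse:
    def test_minimal_root_only_taxonomy(self):
        idx = parse_taxonomy_dump(
            _dmp([(1, "root", "", "scientific name")]), _dmp([(1, 1, "no rank")])
        )
        assert len(idx.nodes) == 1
        assert idx.max_tax_id == 1
        assert idx.minted_ids == []

    def test_six_node_fixture_lineages_reach_root(self, index):
        assert len(index.nodes) == 6
        assert index.max_tax_id == 6
        for species_id in (5, 6):
            lin = index.lineage(species_id)
            assert lin[-1][2] == 1 and len(lin) <= 5

    def test_wrong_field_count_names_line_number(self):
        bad = NODES_TEXT + "7\t|\t4\t|\n"  # 2 fields only
        with pytest.raises(TaxdumpParseError, match="line 7"):
            parse_taxonomy_dump(NAMES_TEXT, bad)

    def test_duplicate_tax_id_rejected(self):
        bad = NODES_TEXT + "6\t|\t4\t|\tspecies\t|\n"
        with pytest.raises(TaxdumpParseError, match="duplicate"):
            parse_taxonomy_dump(NAMES_TEXT, bad)

    def test_missing_scientific_name_rejected(self):
        nodes = NODES_TEXT + "7\t|\t4\t|\tspecies\t|\n"
        with pytest.raises(TaxdumpParseError, match="scientific name"):
            parse_taxonomy_dump(NAMES_TEXT, nodes)

    def test_missing_parent_rejected(self):
        nodes = NODES_TEXT + "7\t|\t99\t|\tspecies\t|\n"
        names = NAMES_TEXT + _dmp([(7, "Abra ghost", "", "scientific name")])
        with pytest.raises(TaxdumpParseError, match="parent"):
            parse_taxonomy_dump(names, nodes)


class TestResolve:
    def test_scientific_name_exact(self, index):
        res = index.resolve_name("Abra alba")
        assert (res.tax_id, res.match_class) == (5, "exact_scientific")
        assert not res.ambiguous and not res.minted

    def test_synonym_class_retains_taxid(self, index):
        res = index.resolve_name("Abra fusca")
        assert (res.tax_id, res.match_class) == (6, "synonym")

    def test_common_name_is_not_eligible(self, index):
        assert index.resolve_name("white furrow shell").match_class == "unresolved"

    def test_unknown_name_unresolved(self, index):
        res = index.resolve_name("Nonexistens dubius")
        assert res.tax_id is None and res.match_class == "unresolved"

    def test_matching_is_case_and_whitespace_insensitive(self, index):
        assert index.resolve_name("  abra   ALBA ").tax_id == 5

    def test_homonym_resolves_to_lowest_taxid_with_flag(self, index):
        # plant a homonym: same name, second tax_id
        from coiref.taxonomy import NameRecord, TaxonomyNode

        index._add_node(TaxonomyNode(7, 2, "genus"))
        index._add_name(NameRecord(7, "Duplex", "scientific name"))
        index._add_node(TaxonomyNode(8, 7, "species"))
        index._add_name(NameRecord(8, "Abra alba", "scientific name"))
        res = index.resolve_name("Abra alba")
        assert res.tax_id == 5 and res.ambiguous

    def test_homonym_focal_lineage_disambiguation(self, index):
        from coiref.taxonomy import NameRecord, TaxonomyNode

        index._add_node(TaxonomyNode(7, 2, "genus"))
        index._add_name(NameRecord(7, "Duplex", "scientific name"))
        index._add_node(TaxonomyNode(8, 7, "species"))
        index._add_name(NameRecord(8, "Abra alba", "scientific name"))
        res = index.resolve_name("Abra alba", focal_tax_ids={7})
        assert res.tax_id == 8 and res.ambiguous


class TestMint:
    def test_mint_is_max_plus_one_under_genus(self, index):
        new_id = index.mint_taxid("Abra exemplum", 4)
        assert new_id == 7
        assert index.nodes[7].parent_id == 4
        assert index.nodes[7].rank == "species"
        assert index.resolve_name("Abra exemplum").tax_id == 7
        assert index.minted_ids == [7]

    def test_successive_mints_are_consecutive(self, index):
        assert index.mint_taxid("Abra prima", 4) == 7
        assert index.mint_taxid("Abra secunda", 4) == 8
        assert index.minted_ids == [7, 8]

    def test_mint_under_unknown_genus_errors(self, index):
        with pytest.raises(TaxonomyError):
            index.mint_taxid("Abra tertia", 999)

    def test_mint_of_resolvable_name_errors(self, index):
        with pytest.raises(TaxonomyError):
            index.mint_taxid("Abra alba", 4)

    def test_minted_lineage_passes_through_genus(self, index):
        new_id = index.mint_taxid("Abra exemplum", 4)
        assert [t for _, _, t in index.lineage(new_id)] == [new_id, 4, 3, 2, 1]

    def test_replay_yields_identical_ids(self):
        ids = []
        for _ in range(2):
            idx = parse_taxonomy_dump(NAMES_TEXT, NODES_TEXT)
            ids.append([idx.mint_taxid("Abra prima", 4), idx.mint_taxid("Abra secunda", 4)])
        assert ids[0] == ids[1]


class TestLineageAndSubtaxa:
    def test_root_lineage_is_single_element(self, index):
        assert index.lineage(1) == [("no rank", "root", 1)]

    def test_unknown_taxid_errors(self, index):
        with pytest.raises(TaxonomyError):
            index.lineage(999)

    def test_family_expands_to_its_species(self, index):
        names, unresolved = index.expand_subtaxa(["Abridae"], rank_filter="species")
        assert names == ["Abra alba", "Abra nitida"]
        assert unresolved == []

    def test_leaf_species_has_no_proper_descendants(self, index):
        names, _ = index.expand_subtaxa(["Abra alba"], rank_filter="species")
        assert names == []

    def test_unknown_focal_name_reported_not_fatal(self, index):
        names, unresolved = index.expand_subtaxa(
            ["Abridae", "Fantasia"], rank_filter="species"
        )
        assert names == ["Abra alba", "Abra nitida"]
        assert unresolved == ["Fantasia"]


class TestRoundTrip:
    def _name_set(self, idx):
        return {
            (r.tax_id, r.name_txt, r.name_class)
            for recs in idx.names.values()
            for r in recs
        }

    def test_fixture_round_trip_preserves_counts(self, index):
        names, nodes = write_taxonomy_dump(index)
        again = parse_taxonomy_dump(names, nodes)
        assert again.nodes == index.nodes
        assert self._name_set(again) == self._name_set(index)
        assert again.max_tax_id == index.max_tax_id

    def test_mint_adds_one_nodes_line(self, index):
        before = write_taxonomy_dump(index)[1].count("\n")
        index.mint_taxid("Abra exemplum", 4)
        after = write_taxonomy_dump(index)[1].count("\n")
        assert after == before + 1

    def test_root_only_round_trip(self):
        idx = parse_taxonomy_dump(
            _dmp([(1, "root", "", "scientific name")]), _dmp([(1, 1, "no rank")])
        )
        names, nodes = write_taxonomy_dump(idx)
        assert nodes.count("\n") == 1
        assert parse_taxonomy_dump(names, nodes).nodes == idx.nodes

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        fam=st.integers(1, 4),
        gen=st.integers(1, 3),
        spp=st.integers(1, 4),
        syn=st.floats(0, 1),
    )
    def test_random_taxonomies_round_trip(self, seed, fam, gen, spp, syn):
        spec = FixtureSpec(
            seed=seed,
            n_families=fam,
            n_genera_per_family=gen,
            n_species_per_genus=spp,
            synonym_fraction=syn,
        )
        names, nodes = make_taxonomy(spec)
        idx = parse_taxonomy_dump(names, nodes)
        names2, nodes2 = write_taxonomy_dump(idx)
        again = parse_taxonomy_dump(names2, nodes2)
        assert again.nodes == idx.nodes
        assert self._name_set(again) == self._name_set(idx)
        assert again.max_tax_id == idx.max_tax_id
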