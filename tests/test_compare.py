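"""Composition statistics and partitioned Jaccard beta-diversity."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from coiref import (
    interpret_ratio,
    jaccard_partition,
    pairwise_beta,
    presence_absence_matrix,
    species_set,
    stats_from_counts,
)
from coiref.records import ReferenceDatabase, SeqRecord


def brute_force_abc(set_a, set_b):
    """Independent oracle: count a, b, c by enumerating element membership."""
    a = b = c = 0
    for element in set_a | set_b:
        in_a, in_b = element in set_a, element in set_b
        if in_a and in_b:
            a += 1
        elif in_a:
            b += 1
        else:
            c += 1
    return a, b, c


def _species_db(*name_level_pairs):
    records = []
    for i, (name, level) in enumerate(name_level_pairs):
        rec = SeqRecord(f"R{i}", "genbank", name, "COI", "ACGT" + "A" * i)
        rec.canonical_name, rec.name_level, rec.tax_id = name, level, 100 + i
        records.append(rec)
    return ReferenceDatabase(records=records)


class TestSpeciesSet:
    def test_only_unique_binomials_counted(self):
        db = _species_db(
            ("Abra alba", "species"), ("Abra alba", "species"), ("Abra", "genus")
        )
        assert species_set(db) == {"Abra alba"}

    def test_empty_db(self):
        assert species_set(ReferenceDatabase()) == set()

    def test_all_genus_level_gives_empty_set(self):
        db = _species_db(("Abra", "genus"), ("Tellina", "genus"))
        assert species_set(db) == set()


class TestStats:
    def test_percentages_from_large_count_table(self):
        s = stats_from_counts(1_491_691, 71_499, 19_154)
        assert s.pct_unique_species == 4.79
        assert s.pct_marine_species == 26.79

    def test_degenerate_all_equal(self):
        s = stats_from_counts(5, 5, 5)
        assert s.pct_unique_species == 100.00
        assert s.pct_marine_species == 100.00

    def test_empty_database_percentages_undefined(self):
        s = stats_from_counts(0, 0, 0)
        assert s.pct_unique_species is None
        assert s.pct_marine_species is None

    def test_count_ordering_enforced(self):
        with pytest.raises(ValueError):
            stats_from_counts(10, 5, 7)

    def test_half_up_rounding(self):
        # 1/800 = 0.125% -> 0.13 under half-up (0.12 under banker's)
        assert stats_from_counts(800, 1, 0).pct_unique_species == 0.13


class TestJaccardPartition:
    def test_identical_sets_zero_dissimilarity_undefined_ratio(self):
        pair = jaccard_partition({"w", "x"}, {"w", "x"})
        assert pair.beta_jac == pair.beta_jtu == pair.beta_jne == 0
        assert pair.beta_ratio is None
        with pytest.raises(ValueError):
            interpret_ratio(pair.beta_ratio)

    def test_pure_nestedness(self):
        pair = jaccard_partition({"w", "x", "y", "z"}, {"w", "x"})
        assert (pair.shared, pair.only_a, pair.only_b) == (2, 2, 0)
        assert pair.beta_jtu == 0
        assert pair.beta_jac == 0.5
        assert pair.beta_jne == 0.5
        assert pair.beta_ratio == 1

    def test_pure_turnover(self):
        pair = jaccard_partition({"p", "q", "r"}, {"r", "s", "t"})
        assert (pair.shared, pair.only_a, pair.only_b) == (1, 2, 2)
        assert pair.beta_jac == 0.8
        assert pair.beta_jtu == 0.8
        assert pair.beta_jne == 0
        assert pair.beta_ratio == 0

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            jaccard_partition(set(), set())

    def test_symmetry(self):
        a, b = {"p", "q", "r", "s"}, {"r", "s", "t"}
        ab, ba = jaccard_partition(a, b), jaccard_partition(b, a)
        assert (ab.beta_jac, ab.beta_jtu, ab.beta_jne) == (
            ba.beta_jac, ba.beta_jtu, ba.beta_jne,
        )

    @settings(max_examples=300, deadline=None)
    @given(
        a=st.sets(st.integers(0, 39), max_size=20),
        b=st.sets(st.integers(0, 39), max_size=20),
    )
    def test_oracle_equivalence_and_additivity(self, a, b):
        if not (a or b):
            return
        a = {f"sp{i}" for i in a}
        b = {f"sp{i}" for i in b}
        pair = jaccard_partition(a, b)
        oa, ob, oc = brute_force_abc(a, b)
        assert (pair.shared, pair.only_a, pair.only_b) == (oa, ob, oc)
        assert pair.beta_jac == pytest.approx((ob + oc) / (oa + ob + oc), abs=0)
        m = min(ob, oc)
        expected_jtu = (2 * m) / (oa + 2 * m) if (oa + 2 * m) else 0.0
        assert pair.beta_jtu == pytest.approx(expected_jtu, abs=0)
        assert abs(pair.beta_jac - (pair.beta_jtu + pair.beta_jne)) <= 1e-12
        assert 0 <= pair.beta_jtu <= pair.beta_jac <= 1

    def test_monotonicity_growing_nestedness_never_raises_turnover(self):
        rng = random.Random(42)
        universe = [f"sp{i}" for i in range(30)]
        fixed_a = set(rng.sample(universe, 15))
        b = set(rng.sample(sorted(fixed_a), 3))
        last_jtu = jaccard_partition(fixed_a, b).beta_jtu
        for element in sorted(fixed_a - b):
            b.add(element)  # adding elements of A only
            jtu = jaccard_partition(fixed_a, b).beta_jtu
            assert jtu <= last_jtu + 1e-12
            last_jtu = jtu


class TestPairwise:
    def test_matrix_entries_equal_per_pair_calls(self):
        sets = {
            "one": {"a", "b", "c"},
            "two": {"b", "c", "d"},
            "three": {"x", "y"},
        }
        mats = pairwise_beta(sets)
        for i in sets:
            for j in sets:
                if i == j:
                    continue
                pair = jaccard_partition(sets[i], sets[j])
                assert mats["beta_jac"].loc[i, j] == pair.beta_jac
                assert mats["beta_jtu"].loc[i, j] == pair.beta_jtu

    def test_symmetric_with_zero_diagonals(self):
        sets = {"one": {"a", "b"}, "two": {"b", "c"}}
        mats = pairwise_beta(sets)
        for key in ("beta_jac", "beta_jtu", "beta_jne"):
            assert (mats[key].values == mats[key].values.T).all()
            assert (mats[key].values.diagonal() == 0).all()
        assert math.isnan(mats["beta_ratio"].loc["one", "one"])

    def test_duplicate_database_gives_zero_off_diagonal(self):
        sets = {"one": {"a", "b"}, "copy": {"a", "b"}}
        mats = pairwise_beta(sets)
        assert mats["beta_jac"].loc["one", "copy"] == 0

    def test_nested_chain_all_ratios_one(self):
        chain = {
            "big": {"a", "b", "c", "d", "e", "f"},
            "mid": {"a", "b", "c", "d"},
            "small": {"a", "b"},
        }
        mats = pairwise_beta(chain)
        for i in chain:
            for j in chain:
                if i != j:
                    assert mats["beta_ratio"].loc[i, j] == 1

    def test_fewer_than_two_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_beta({"only": {"a"}})

    def test_presence_absence_matrix_shape(self):
        sets = {"one": {"a", "b"}, "two": {"b"}}
        pa = presence_absence_matrix(sets)
        assert list(pa.index) == ["a", "b"]
        assert pa.loc["b", "one"] == 1 and pa.loc["a", "two"] == 0


@pytest.mark.parametrize(
    "ratio, expected",
    [
        (0.04, "turnover_dominated"),
        (0.06, "turnover_dominated"),
        (0.10, "turnover_dominated"),
        (0.92, "nestedness_dominated"),
        (0.5, "balanced"),
    ],
)
def test_interpret_ratio_threshold(ratio, expected):
    assert interpret_ratio(ratio) == expected
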