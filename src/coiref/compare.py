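"""Database composition statistics and partitioned Jaccard beta-diversity.

Two reference databases are compared on species presence/absence.  Total
Jaccard dissimilarity splits into a turnover component (species substitution)
and a nestedness-resultant component (richness difference) following
Baselga's partition.  With a = |A∩B| shared species, b = |A\\B| and
c = |B\\A|:

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2*min(b, c) / (a + 2*min(b, c))
    beta_jne = beta_jac - beta_jtu
    beta_ratio = beta_jne / beta_jac        (undefined when beta_jac = 0)

A beta_ratio below 0.5 means the difference between two databases is mostly
species turnover; above 0.5 it is mostly a richness (nestedness) effect —
one database is largely a subset of the other.

Species identity is the canonical binomial string, case-insensitive, because
TaxIDs are not comparable across independently normalized databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .records import ReferenceDatabase
from .taxonomy import normalize_name


def species_set(db: ReferenceDatabase) -> set[str]:
    """Unique canonical binomials of species-level records.

    Genus-level and unusable names are excluded: only fully identified taxa
    with binomial species names enter composition statistics.  Deduplication
    is case-insensitive, keeping the first-seen spelling.
    """
    seen: dict[str, str] = {}
    for rec in db.records:
        if rec.name_level == "species" and rec.canonical_name:
            seen.setdefault(normalize_name(rec.canonical_name), rec.canonical_name)
    return set(seen.values())


def _round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (exact decimal arithmetic)."""
    pct = Decimal(numerator * 100) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DatabaseStats:
    """Composition summary of one reference database.

    ``pct_unique_species`` = 100 * unique species / total sequences;
    ``pct_marine_species`` = 100 * marine species / unique species.
    Percentages are ``None`` when their denominator is zero.
    """

    n_sequences: int
    n_unique_species: int
    n_marine_species: int
    pct_unique_species: Optional[float]
    pct_marine_species: Optional[float]


def stats_from_counts(
    n_sequences: int, n_unique_species: int, n_marine_species: int
) -> DatabaseStats:
    """Compute the percentage fields from raw counts."""
    if not 0 <= n_marine_species <= n_unique_species <= n_sequences:
        raise ValueError("counts must satisfy marine <= unique <= sequences")
    return DatabaseStats(
        n_sequences=n_sequences,
        n_unique_species=n_unique_species,
        n_marine_species=n_marine_species,
        pct_unique_species=(
            _round_pct(n_unique_species, n_sequences) if n_sequences else None
        ),
        pct_marine_species=(
            _round_pct(n_marine_species, n_unique_species) if n_unique_species else None
        ),
    )


def db_stats(db: ReferenceDatabase) -> DatabaseStats:
    """Composition statistics of a normalized, marine-screened database."""
    species = species_set(db)
    marine = {
        normalize_name(rec.canonical_name)
        for rec in db.records
        if "marine" in rec.flags and rec.name_level == "species" and rec.canonical_name
    }
    return stats_from_counts(len(db.records), len(species), len(marine))


@dataclass
class BetaPair:
    """Partitioned Jaccard dissimilarity for one database pair."""

    shared: int  # a
    only_a: int  # b
    only_b: int  # c
    beta_jac: float
    beta_jtu: float
    beta_jne: float
    beta_ratio: Optional[float]  # None when beta_jac == 0


def jaccard_partition(set_a: Iterable[str], set_b: Iterable[str]) -> BetaPair:
    """Baselga partition of Jaccard dissimilarity between two species sets."""
    a_keys = {normalize_name(s) for s in set_a}
    b_keys = {normalize_name(s) for s in set_b}
    if not a_keys and not b_keys:
        raise ValueError("both species sets are empty")
    a = len(a_keys & b_keys)
    b = len(a_keys - b_keys)
    c = len(b_keys - a_keys)
    beta_jac = (b + c) / (a + b + c)
    m = min(b, c)
    beta_jtu = (2 * m) / (a + 2 * m) if (a + 2 * m) else 0.0
    beta_jne = beta_jac - beta_jtu
    beta_ratio = beta_jne / beta_jac if beta_jac > 0 else None
    return BetaPair(a, b, c, beta_jac, beta_jtu, beta_jne, beta_ratio)


DatabaseLike = Union[ReferenceDatabase, set, frozenset, list, tuple]


def _as_species_set(obj: DatabaseLike) -> set[str]:
    if isinstance(obj, ReferenceDatabase):
        return species_set(obj)
    return set(obj)


def pairwise_beta(dbs: Mapping[str, DatabaseLike]) -> dict[str, pd.DataFrame]:
    """All-pairs beta matrices for >=2 named databases (or raw species sets).

    Returns symmetric DataFrames keyed ``beta_jac``, ``beta_jtu``,
    ``beta_jne`` and ``beta_ratio``; diagonals are 0 except the beta_ratio
    diagonal, which is undefined (NaN), as are off-diagonal ratios of
    identical sets.
    """
    if len(dbs) < 2:
        raise ValueError("pairwise comparison needs at least 2 databases")
    names = list(dbs)
    sets = {n: _as_species_set(v) for n, v in dbs.items()}
    mats = {
        k: pd.DataFrame(0.0, index=names, columns=names, dtype=float)
        for k in ("beta_jac", "beta_jtu", "beta_jne", "beta_ratio")
    }
    mats["beta_ratio"].values[:] = float("nan")
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            pair = jaccard_partition(sets[ni], sets[nj])
            for key, val in (
                ("beta_jac", pair.beta_jac),
                ("beta_jtu", pair.beta_jtu),
                ("beta_jne", pair.beta_jne),
                ("beta_ratio", pair.beta_ratio if pair.beta_ratio is not None else float("nan")),
            ):
                mats[key].loc[ni, nj] = val
                mats[key].loc[nj, ni] = val
    return mats


def presence_absence_matrix(dbs: Mapping[str, DatabaseLike]) -> pd.DataFrame:
    """0/1 matrix: rows = species (sorted), columns = database names."""
    sets = {n: {normalize_name(s) for s in _as_species_set(v)} for n, v in dbs.items()}
    all_species = sorted(set().union(*sets.values())) if sets else []
    return pd.DataFrame(
        {n: [int(sp in sets[n]) for sp in all_species] for n in sets},
        index=all_species,
    )


def interpret_ratio(beta_ratio: Optional[float]) -> str:
    """Classify a beta_ratio against the 0.5 threshold.

    Below 0.5 the dissimilarity is turnover-dominated (different species);
    above 0.5 it is nestedness-dominated (richness-driven).
    """
    if beta_ratio is None:
        raise ValueError("beta_ratio is undefined (beta_jac = 0)")
    if beta_ratio < 0.5:
        return "turnover_dominated"
    if beta_ratio > 0.5:
        return "nestedness_dominated"
    return "balanced"


def stats_to_tsv(stats: Mapping[str, DatabaseStats]) -> str:
    """Composition table as TSV (one row per database)."""
    header = (
        "database\tn_sequences\tn_unique_species\tpct_unique_species"
        "\tn_marine_species\tpct_marine_species"
    )
    rows = [header]
    for name, s in stats.items():
        rows.append(
            f"{name}\t{s.n_sequences}\t{s.n_unique_species}\t"
            f"{'' if s.pct_unique_species is None else s.pct_unique_species}\t"
            f"{s.n_marine_species}\t"
            f"{'' if s.pct_marine_species is None else s.pct_marine_species}"
        )
    return "\n".join(rows) + "\n"
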