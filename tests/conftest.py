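"""Shared hand-written micro-fixtures.

The taxonomy dump and the GenBank/BOLD texts below were transcribed by hand
(and hand-parsed for the oracle expectations in the unit tests); generated
fixtures come from :mod:`coiref.simulate` at test time.
"""

import pytest

from coiref import parse_taxonomy_dump


def _dmp(rows):
    return "".join("\t|\t".join(str(f) for f in row) + "\t|\n" for row in rows)


# root -> kingdom -> family -> genus -> 2 species; one species has a synonym.
NODES_TEXT = _dmp(
    [
        (1, 1, "no rank"),
        (2, 1, "kingdom"),
        (3, 2, "family"),
        (4, 3, "genus"),
        (5, 4, "species"),
        (6, 4, "species"),
    ]
)

NAMES_TEXT = _dmp(
    [
        (1, "root", "", "scientific name"),
        (2, "Eukaryota", "", "scientific name"),
        (3, "Abridae", "", "scientific name"),
        (4, "Abra", "", "scientific name"),
        (5, "Abra alba", "", "scientific name"),
        (6, "Abra nitida", "", "scientific name"),
        (6, "Abra fusca", "", "synonym"),
        (5, "white furrow shell", "", "common name"),
    ]
)

GENBANK_TEXT = """\
LOCUS       AB000001                  60 bp    DNA     linear   INV 01-JAN-2010
DEFINITION  Abra alba cytochrome oxidase subunit 1 (COI) gene, partial cds.
ACCESSION   AB000001
VERSION     AB000001.1
SOURCE      Abra alba
  ORGANISM  Abra alba
            Eukaryota; Mollusca; Bivalvia.
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
LOCUS       AB000002                  20 bp    DNA     linear   INV 01-JAN-2010
DEFINITION  Abra nitida COI gene.
ACCESSION   AB000002
VERSION     AB000002.2
SOURCE      Abra nitida
  ORGANISM  Abra nitida
            Eukaryota; Mollusca.
ORIGIN
        1 ttggcaatga aagtcgtaac
//
"""

GENBANK_NO_ORGANISM_ENTRY = """\
LOCUS       AB000003                  20 bp    DNA     linear   INV 01-JAN-2010
DEFINITION  organism block absent.
ACCESSION   AB000003
VERSION     AB000003.1
ORIGIN
        1 ttggcaatga aagtcgtaca
//
"""

BOLD_TEXT = (
    "processid\tspecies_name\tgenus_name\tmarkercode\tnucleotides\n"
    "PROC001\tAbra alba\tAbra\tCOI-5P\tACGT-ACGTAC--GTACGTTTGA\n"
    "PROC002\tAbra nitida\tAbra\tCOI-5P\tGGGTTTACGTACGTACGTAA\n"
    "PROC003\tAbra fusca\tAbra\tCOI-5P\t\n"
)


@pytest.fixture
def index():
    """Freshly parsed 6-node taxonomy (mutable; safe to mint into)."""
    return parse_taxonomy_dump(NAMES_TEXT, NODES_TEXT)
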