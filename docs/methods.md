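# Methods

This note documents the models, rules and numerical choices behind `coiref`,
the assumptions they rest on, and what the test suite does and does not
demonstrate.

## Taxonomy model

The local taxonomy is an in-memory copy of an NCBI-style taxdump: a rooted
tree of `(tax_id, parent_id, rank)` nodes plus a multimap of names with name
classes. Only those fields are interpreted; the writer emits the standard
13-field `nodes.dmp` / 4-field `names.dmp` layout (unused columns empty,
records terminated `\t|`) so downstream tools that consume taxdumps —
`kraken2-build` in particular — accept the output, including locally minted
nodes. Parsing validates the tree by walking every node to the root, which
catches missing parents and cycles; each node must carry exactly one
scientific name.

**Name resolution.** Matching is case-insensitive with internal whitespace
collapsed, and never fuzzy — a misspelled name should fail visibly rather
than silently attach to the wrong taxon. Scientific names take precedence;
if none match, the synonym-type classes `synonym`, `equivalent name`,
`includes` and `genbank synonym` are consulted (mirroring GenBank
TaxIdentifier behaviour). `common name` is deliberately ineligible.

**Homonyms.** One name string can map to several TaxIDs (a real hazard for
algae/animal homonyms across kingdoms). Policy: if a focal-taxon set is
supplied and exactly one candidate's lineage intersects it, that candidate
wins; otherwise the lowest TaxID wins. Either way the resolution — and the
record it is attached to — is flagged `ambiguous_homonym`, so the choice is
deterministic *and* auditable. This is a documented convention, not a fact
about nature.

**Minting.** A species name that cannot be resolved, but whose genus can, is
assigned a new TaxID equal to `max_tax_id + 1` at mint time, inserted as a
species-rank node under the genus. Consequences worth noting: minted IDs are
deterministic given the taxonomy state (replaying the same inputs yields the
same IDs) but depend on the taxonomy version; names are deduplicated before
the cascade so one unresolvable name mints exactly once no matter how many
records carry it. Genus-level names ("Abra sp.") take the genus TaxID
directly — no node is created. Taxa whose genus is also unknown cannot be
rescued and are dropped; extending minting above genus level is intentionally
not implemented.

## Binomial extraction

Organism strings are reduced to a canonical name and a level before
resolution. Qualifier tokens (`sp`, `spp`, `cf`, `aff`, `nr`, `gen`,
`indet`, `complex`, `group`, with or without a trailing dot) and quoted
epithets are discarded. Then: a capitalized first word followed by a clean
lowercase epithet is a species-level binomial (trinomials truncate to the
first two words); a capitalized first word alone — or followed only by
discarded/unclean tokens — is genus-level; anything else is unusable. A bare
genus is treated as genus-level rather than unusable so that BOLD rows
lacking a species name but carrying a genus column remain assignable at genus
level.

## Dereplication

Duplicates are *exact, full-length, case-insensitive* string matches after
canonicalization (gaps stripped, uppercased) — the semantics of vsearch's
standard `--derep_fulllength`, chosen because it is reversible to audit:
the cluster map (kept accession → collapsed accessions) is retained in the
derivation log. Prefix dereplication and similarity clustering are out of
scope. Reverse complements are **not** treated as duplicates; COI barcode
submissions are overwhelmingly deposited in a consistent orientation, and
collapsing reverse complements would silently discard orientation
information. Ties go to the first record in merged order (GenBank-derived
before BOLD-derived, each in input order); when collapsed records disagree on
the organism name, the kept record's name wins and the conflict is reported.

## Screening

Checklist matching is by *name* at family and species rank, case-insensitive,
not by TaxID — the marine register and the NCBI taxonomy are different
nomenclatures, so a name-level cross-walk is the only stable join. A record
is marine if its species binomial is listed or its lineage passes through a
listed family; family-level inclusion deliberately keeps terrestrial
relatives inside marine families so reads can still be assigned at genus or
family level. Records whose lineage lacks a family rank are evaluated on the
species set only and tallied. Marine and contaminant flags are independent
(a record can be both). Contaminant policies: `flag` (mark only), `remove`
(drop; removed set plus output partition the input), `merge` (keep, flagged).

## Composition statistics and β-diversity

`% unique species` divides unique species-level binomials by total sequences;
`% marine species` divides marine species by unique species. Percentages are
rounded **half-up** to two decimals using exact decimal arithmetic; this
convention reproduces twelve of the fourteen percentage cells derivable from
the printed counts of seven published COI reference databases. The remaining
two printed cells (a unique-species percentage of 4.91 where the printed
counts give 4.99, and one of 9.10 where the counts give 9.09) are
inconsistent with their own printed numerators and denominators under any
2-decimal rounding rule; they are documented here and excluded from the
acceptance checks.

Between-database comparison uses the Baselga partition of Jaccard
dissimilarity on species presence/absence: with `a` shared and `b`, `c`
side-unique species, `β_jac = (b+c)/(a+b+c)`,
`β_jtu = 2·min(b,c)/(a+2·min(b,c))`, `β_jne = β_jac − β_jtu`, and
`β_ratio = β_jne/β_jac`, classified against 0.5 (below: turnover-dominated;
above: nestedness-dominated). `β_ratio` is **undefined** at `β_jac = 0`
(identical sets): it is 0/0, and imputing either 0 or 1 would misstate which
component dominates, so the API returns a null and the matrices carry NaN.
Species identity for these matrices is the canonical binomial string,
case-insensitive, because TaxIDs minted locally are not comparable across
independently normalized databases. The implementation is verified against a
brute-force membership counter (an independent oracle that enumerates
elements to count `a`, `b`, `c`) rather than against another library, and the
additivity `β_jac = β_jtu + β_jne` holds to 1e-12 by construction.

The published β matrices for repository-scale databases are not reproduced:
that would require downloading the repositories themselves. The package's
claim is that the *machinery* is exact (oracle equivalence, the pure-nestedness
and pure-turnover limits, symmetry, additivity), not that it has re-measured
the published databases.

## Export formats

Kraken2 headers follow `>accession|kraken:taxid|TaxID` (regex-checked for
every record); MEGAN and BLAST exports pair a normalized FASTA
(`>accession;taxlabel=<name>;taxid=<id>;gene=<label>`) with an
accession→TaxID map (tab-separated for MEGAN tooling, space-separated in the
`makeblastdb -taxid_map` dialect). MEGAN's expected header dialect is not
standardized anywhere authoritative; the accession-map form is this package's
documented choice. FASTA wraps at 80 columns — conventional, and fixed so
outputs are bit-stable. Exports require unique accessions and a TaxID on
every record; both are hard errors, not warnings, because silent taxid loss
poisons downstream LCA assignment. Invoking `kraken2-build`/`makeblastdb` is
left to the user: the files are the contract.

## The fixture generator

`coiref.simulate` generates the study conditions for all testing: a taxonomy
of configurable shape (default 3 families × 2 genera × 3 species, with a
kingdom layer and a root), two repository files whose species sets overlap by
a configurable fraction (default 0.5), and planted events at fixed rates —
15 % duplicated records (planted by copying, since at 120 bp random DNA a
chance collision is ~4⁻¹²⁰; uniqueness of all other sequences is enforced),
20 % of species carrying a synonym (all their records use it), 15 % novel
species requiring a mint, 10 % unresolvable records, 5 % blacklisted extras,
60 % of families marine, one genus-only BOLD row and one empty-nucleotides
BOLD row. GenBank text is written through Biopython's flatfile writer; BOLD
rows carry one planted alignment gap each to exercise gap stripping. Every
planted fact goes into a truth table, and the acceptance suite replays 20
randomized specifications end to end, requiring *exact* recovery of every
count (duplicates collapsed, mints and their IDs, drops, marine flags and
species counts, contaminant removals, final species sets).

What the generator does **not** emulate: real COI sequence evolution, primer
or amplicon structure, length variation, repository metadata noise beyond the
planted cases, and the sheer scale of the real repositories. Passing tests
therefore demonstrate that the curation logic is exact under controlled
conditions, not that name-matching heuristics cover the full messiness of
real repository metadata.

## Determinism and sizes

One seed drives each fixture; per-section generators are derived as
`"{seed}-tree"`, `"{seed}-repo"`, `"{seed}-checklist"`, `"{seed}-names"`,
`"{seed}-bold-gaps"`, so artifacts are independently reproducible and the
same seed is byte-identical. Default problem sizes (tens of species, ~40
records per run, 50 round-trip seeds, 20 pipeline replicates, 1000 random
set pairs) keep the whole suite and the acceptance script within seconds
while still exercising every branch; they are the package's chosen study
conditions, documented here once.

## Known limitations

- Minting requires a resolvable genus; family-only names are dropped.
- No merged.dmp/delnodes.dmp handling; the local taxonomy is assumed
  internally consistent.
- Live NCBI/BOLD retrieval ships as optional, untested adapters
  (`coiref.adapters`); the supported path is local files.
- Checklist screening is binary (marine / not); no habitat attributes.
- The homonym policy is a convention; genuinely ambiguous names should be
  audited via the `ambiguous_homonym` flag rather than trusted.
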