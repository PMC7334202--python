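# coiref

A curation toolkit for building **COI metabarcoding reference databases**
from GenBank- and BOLD-style inputs, unifying them under a single NCBI-style
taxonomy, and exporting them ready for the common taxonomic-assignment tools
(Kraken2, MEGAN, BLAST).

## The problem

Metabarcoding studies identify the taxa in environmental or community samples
by matching amplicon reads of a marker gene — for animals, usually cytochrome
c oxidase subunit 1 (COI, synonyms CO1/COX1/COXI) — against a reference
database of taxonomically assigned sequences. The two main COI repositories,
GenBank and BOLD, overlap only partially and use different taxonomies, so a
comprehensive database has to merge both and then *normalize* the taxonomy:
every reference sequence needs an NCBI TaxID, because assignment algorithms
(lowest-common-ancestor classifiers in MEGAN, Kraken2, ecotag) operate on the
taxonomy tree. `coiref` implements that curation pipeline end to end:

1. **Ingest** GenBank flatfiles and BOLD-style TSV exports into a common
   record model (plus Entrez-style search-term construction, with or without
   the `barcode` keyword).
2. **Blacklist & merge** — drop suspect accessions, concatenate the two sets.
3. **Dereplicate** — collapse exact full-length duplicate sequences
   (vsearch-style `--derep_fulllength` semantics) to the first-seen record.
4. **Normalize taxonomy** — resolve each name against `names.dmp`/`nodes.dmp`
   (scientific names first, then synonym classes, case-insensitively).
   A species absent from the taxonomy but with a known genus receives a
   **minted TaxID**: `max_tax_id + 1`, inserted as a species-rank node under
   the genus; records that cannot be resolved or minted are removed.
5. **Screen** records against a marine checklist (WoRMS-style families and/or
   species) and a contaminant list (flag, remove, or merge).
6. **Export** Kraken2 FASTA (`>acc|kraken:taxid|ID`), MEGAN/BLAST FASTA plus
   accession→TaxID maps, and the extended taxdump including minted nodes.

## Comparing databases

Composition statistics follow the conventional table layout:
`% unique species = 100 · S / N` (unique binomial species over total
sequences) and `% marine species = 100 · M / S` (marine species over unique
species), rounded half-up to two decimals.

Pairwise differences between databases use the Baselga partition of Jaccard
dissimilarity on species presence/absence. With `a` shared species and `b`,
`c` unique to either side:

```
β_jac = (b+c)/(a+b+c)         total dissimilarity
β_jtu = 2·min(b,c)/(a+2·min(b,c))   turnover component
β_jne = β_jac − β_jtu          nestedness-resultant component
β_ratio = β_jne/β_jac          (<0.5 turnover-dominated, >0.5 nestedness-dominated)
```

## Worked example

No downloads are needed: `coiref.simulate` generates miniature inputs
(taxonomy dump, GenBank flatfile, BOLD TSV, blacklist, checklists) with every
curation branch planted deliberately, plus a truth table of what the pipeline
must find.

```python
from coiref import FixtureSpec, run_fixture_pipeline, jaccard_partition, interpret_ratio

result, fixture = run_fixture_pipeline(FixtureSpec(seed=1), contaminant_policy="remove")
r = result.normalization
print(f"exact={r.n_exact} synonym={r.n_synonym} minted={r.n_minted} dropped={r.n_dropped}")
print(result.stats)

pair = jaccard_partition(fixture.truth.species_set_genbank,
                         fixture.truth.species_set_bold)
print(f"beta_jac={pair.beta_jac:.3f} beta_ratio={pair.beta_ratio:.3f}",
      interpret_ratio(pair.beta_ratio))
```

prints

```
exact=23 synonym=6 minted=3 dropped=2
DatabaseStats(n_sequences=31, n_unique_species=21, n_marine_species=15, pct_unique_species=67.74, pct_marine_species=71.43)
beta_jac=0.591 beta_ratio=0.109 turnover_dominated
```

Reading: of 34 dereplicated records, 23 names matched the taxonomy exactly, 6
through synonyms, 3 novel species were minted under their genera and 2
unresolvable records were dropped; after removing one contaminant record the
database holds 31 sequences covering 21 unique species, 15 of them marine
(71.43 %). The two simulated repositories differ mostly by species turnover
(β_ratio ≈ 0.11), not richness.

The same pipeline is available from the shell:

```bash
coiref make-fixtures --seed 1 --out-dir demo/
coiref run --config demo/config.yaml      # or stage-by-stage subcommands
coiref --help                             # ingest-genbank, ingest-bold, merge,
                                          # normalize, screen, export, stats,
                                          # compare, make-fixtures, run
```

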