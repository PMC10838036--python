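# taxonlink

Harmonise taxon names and database identifiers between the **GBIF
Backbone Taxonomy**, the **NCBI Taxonomy** and **Wikidata**.

A common task in biodiversity informatics is finding sequence data (kept
under NCBI taxonomy identifiers) for a set of species chosen by
occurrence or distribution (kept under GBIF identifiers). Matching the
two by scientific name alone is error-prone: homonyms (one spelling,
independently published for different taxa), synonyms (one taxon under
several names), chresonyms (author citations that refer to a later usage
of a name), merged or deleted identifiers, and plain misspellings all
produce wrong links. `taxonlink` automates the mechanical part of that
reconciliation and turns the rest into an explicit, reviewable curation
queue:

1. **Filter** a GBIF "species list" export to species-rank names and
   resolve each taxonID to its currently accepted backbone record.
2. **Match** the accepted canonical names against the species of one
   NCBI subtree (by default Viridiplantae, NCBI:txid33090 — restricting
   to one kingdom's subtree also keeps hemihomonyms out of the candidate
   pool). Matches are *exact*, *fuzzy* (edit distance ≤ 1 or equality
   after folding the Latin gender endings *-us/-a/-um*), or
   *partial* (genus only; reported but excluded). Exact matches are
   refined by author citation into `exact` / `noauthor` /
   `author_mismatch`, with diacritic and abbreviation normalisation
   ("Hultén" ≡ "Hulten", "Hook.f." ≡ "Hook.fil.").
3. **Second round**: names with no match retry through their GBIF
   synonyms, since the two databases may accept different names for the
   same taxon.
4. **Cross-check with Wikidata**: look the GBIF id up among "GBIF taxon
   ID" (P846) claims; if that fails, look the matched NCBI id up among
   "NCBI taxonomy ID" (P685) claims. Lookups run against an offline TSV
   snapshot; the SPARQL to refresh a snapshot from the live endpoint can
   be generated (`sparql-gen`) but is never executed by the package.
5. **Triage** every name into exactly one curation action via a
   first-match rule table: `a` no match, `b` auto-accept, `c` verify /
   update the NCBI id in Wikidata, `d` batch-add the NCBI id, `e`
   batch-update a stale GBIF id, `f` verify a synonym before linking,
   `g` verify authorship, `h` possible homonym, `other` manual review.
6. **Export batch edits** for actions `d` and `e` in a QuickStatements-
   style text dialect. Stale identifiers are never deleted: they are
   re-added at *deprecated* rank with a "reason for deprecated rank"
   qualifier (P2241 → Q67125514) and a "retrieved" (P813) reference
   date.

A synthetic-world generator produces coherent backbone + checklist +
taxdump + Wikidata snapshot fixtures with each of these pathologies
planted at configured rates and a ground-truth table, so the whole
pipeline is testable offline.

## Worked example

Generate a 100-species world with 5% stale Wikidata links, 5% homonyms
and 5% missing author citations, then run the pipeline:

```sh
$ taxonlink synth --seed 42 --n-species 100 \
    --rate-stale-gbif-link 0.05 --rate-homonym 0.05 --rate-missing-author 0.05 \
    demo/world
world with 100 checklist rows written to demo/world

$ taxonlink run \
    --species-list demo/world/species_list.tsv \
    --backbone demo/world/backbone.tsv \
    --taxdump demo/world/taxdump \
    --wikidata demo/world/wikidata.tsv \
    --reference-kingdom Plantae --retrieved 2023-06-23 \
    --outdir demo/out
a	0
b	85
c	0
d	0
e	5
f	0
g	5
h	5
other	0
```

The per-action summary says: 85 names matched cleanly with identical
authors and consistent Wikidata links (`b`, accepted automatically); the
5 stale Wikidata links were caught (`e`) and turned into batch edits;
the 5 records without author citations (`g`) and the 5 author conflicts
(`h`) were routed to manual-verification queues. `demo/out/curation.tsv`
holds one row per name with all evidence columns, and
`demo/out/qs_update_gbif.txt` contains the edits for action `e`, e.g.:

```
Q20000011	P846	"5000011"	S813	+2023-06-23T00:00:00Z/11
Q20000011	P846	"3000001"	RANK	deprecated	S813	+2023-06-23T00:00:00Z/11
```

— add the current GBIF id, and keep the stale one at deprecated rank.
The stages are also available individually (`taxonlink match`,
`taxonlink triage --matches …`, `taxonlink qs-export`), producing
byte-identical outputs to the single-shot run.

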