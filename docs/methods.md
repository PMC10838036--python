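# Methods

## The reconciliation model

The package links two identifier namespaces that model taxonomy
differently. In the GBIF Backbone every name — accepted or synonym —
has its own taxonID and a taxonomic status, with synonym records
pointing at their accepted record. In the NCBI Taxonomy synonyms are
merged under the accepted name's taxid; superseded taxids survive only
in `merged.dmp` / `delnodes.dmp`. Wikidata holds one item per taxon
name with external identifiers attached as claims (GBIF taxon ID P846,
NCBI taxonomy ID P685). Reconciliation therefore proceeds name-first:
canonical names are matched between the two taxonomies, author
citations arbitrate between identically spelled names, and the
identifier links recorded on Wikidata serve as a third, independent
witness that either corroborates the name match or exposes a stale or
wrong link.

Key assumptions: the checklist's taxonIDs refer to the supplied
backbone version or to predecessors resolvable inside it; restricting
reference names to one NCBI subtree removes cross-kingdom homonyms
(hemihomonyms) from the candidate pool; and author-citation equality —
after normalisation — is sufficient evidence that two identically
spelled names denote the same nomenclatural act. The last assumption
is exactly where chresonyms mislead, which is why author mismatches are
queued for verification rather than rejected outright.

## Name parsing and author comparison

The parser handles the subset of botanical (and basic zoological) name
syntax the workflow needs: uninomials, binomials, infraspecific markers
(`subsp.`/`ssp.` → subsp., `var.`, `f.`), hybrid signs (`×`, standalone
`x`), parenthesised basionym citations, `ex`/`in` author constructions
and trailing years. A bare `f.` is read as the *filius* author
abbreviation unless followed by a lower-case epithet, in which case it
is the forma marker. Parsing is total: anything whose first word does
not look like a genus name is returned unparsed (`quality=unparseable`)
with the verbatim string preserved.

Author tokens are normalised by Unicode NFKD decomposition with
combining marks stripped, case folding, trailing-period removal, and a
segment-wise abbreviation table (shipped as editable YAML, seeded with
`fil ↔ f`). The comparison ladder is:

* **absent** — either side has no citation (the workflow's "noauthor");
* **identical** — verbatim equality after whitespace collapse;
* **normalized_match** — token-normalised author sequences equal,
  basionym and combination authors compared separately; if exactly one
  side records a parenthesised basionym, that side's combination
  authors are compared against the other side's full list first,
  because databases are inconsistent about recording basionyms;
* **mismatch** — everything else; this is the homonym signal.

`ex` chains compare on the final (publishing) author, `in` chains on
the name author; "et" is unified with "&". Years are parsed but ignored
in comparison — the scheme compares citations, not dates. Whether
"identical" should be byte-level or whitespace-insensitive is not
externally fixed; whitespace-collapse equality was chosen, and any pair
that matches only through deeper normalisation is reported as
`normalized_match` with the load-bearing steps listed as evidence.

## Matching

Exact matching is case-insensitive equality of canonical names, served
from a hash index. Fuzzy matching accepts candidates within edit
distance ≤ 1 (computed with `edlib`) plus pairs that become equal after
folding the terminal epithet's Latin gender ending (-us/-a/-um);
stem-folded pairs are marked `stem_fold=True` and carry their true
character edit distance, keeping the "fuzzy implies distance > 0"
invariant while still distinguishing them from misspellings. The
threshold is a parameter; raising it can only add matched queries.
Genus-only agreement is reported as `partial_exact` but flagged
excluded — the exclusion is visible in the match report rather than a
silent drop. Every query yields at least one match record (possibly
`category=none`), so the output partitions the query set.

Multiple candidates are all kept and ranked (author class, then edit
distance, then reference id as a deterministic tie-break). If the top
two candidates tie on author class and distance, the case goes to
manual review instead of trusting an arbitrary winner. When an NCBI
record stores several authority strings, each is tried and the best
outcome kept — the dump genuinely contains multiples.

Queries with no first-round match retry through their GBIF synonyms;
successful second-round matches record the synonym's taxonID, and the
author comparison uses the synonym's citation (the match is an
assertion about the synonym's name, not the accepted name's).

## Evidence and triage

Evidence gathering is forward-first: look the (currently accepted) GBIF
id up on the snapshot; only if that fails, and a name match produced an
NCBI id, look that id up in reverse. A reverse item therefore never
coexists with a forward hit. One row of the outcome table — exact
match, GBIF-linked, no Wikidata NCBI id, but NCBI-reverse-linked — is
unreachable under this contract; the row is kept in the rule list for
completeness.

Triage is a first-match rule list over a finite domain (match type ×
link evidence × GBIF status), with wildcards for conditions a row does
not evaluate and `OTHER` as the fall-through, making the function total
by construction. Two deliberate policies sit on top of the table:

* **Via-synonym demotion.** A match obtained only through a GBIF
  synonym never triggers an automatic action (`b`, `d`, `e`); it is
  demoted to the synonym-verification queue (`f`). Designating a
  synonym is a revisable taxonomic assertion, and auto-linking the
  synonym's NCBI id from the accepted name's item is precisely the edit
  that identifier curation should prevent.
* **Tie demotion.** Exact candidate ties go to `OTHER` (see above).

Homonym flagging is independent of the action: every case whose author
comparison is a genuine mismatch (not an orthographic variant) is
flagged, with kind `hemihomonym` when the checklist kingdom and the
configured reference-subtree kingdom differ, `within_code` otherwise.
The pipeline leaves the reference kingdom empty unless configured,
because the NCBI subtree name ("Viridiplantae") and checklist kingdom
vocabulary ("Plantae") are not directly comparable strings.

## Batch edits

Actions `d` and `e` generate QuickStatements-style commands; the
dialect is documented in `taxonlink/quickstatements.py`. Values are
bare identifiers (never URLs), every statement carries a "retrieved"
(P813) day-precision reference — a required input rather than "today",
for reproducibility — and stale identifiers are re-emitted at
deprecated rank with the P2241 → Q67125514 reason qualifier instead of
being deleted. The line dialect lacks a native rank command, so the
renderer uses a documented `RANK<TAB>deprecated` field pair; a parser
for the dialect ships alongside, and batches round-trip through it.
Only P813 references are emitted for action `e`; a source-URL reference
is a possible extension, left out to keep edits minimal.

## Synthetic worlds

The generator emulates the study conditions: one checklist name per
species, at most one planted pathology per species (compound cases
would make truth labels ambiguous), with pathology rates as fractions
of `n_species`. Distinct species names come from syllable templates and
are rejection-sampled to pairwise edit distance ≥ 3, so a planted
distance-1 misspelling has a unique nearest neighbour. Each pathology
reproduces one real failure mode: stale P846 values, taxids moved to
`merged.dmp`, same-spelling/different-author records with and without
consistent Wikidata links (homonym vs chresonym), missing authority
rows, single-character misspellings, different accepted names reachable
only via a GBIF synonym, and identically named species planted in the
animal subtree. Worlds are byte-identical under a fixed seed.

What the generator does **not** emulate: realistic name-frequency and
string-length distributions, infraspecific checklist entries, multiple
pathologies per name, multi-value Wikidata claims, and the live
churn of real databases. Passing the recovery tests therefore shows the
pipeline implements its own rules correctly on unambiguous inputs; it
does not bound error rates on real checklists, where the manual queues
(`c`, `f`, `g`, `h`, `other`) exist precisely because automation runs
out.

A second, fixed fixture world encodes eight documented curation cases
with their published identifiers (stale sunflower link, merged
*Calamagrostis* taxid, *Rubus gracilis* homonym, doubtful *Willemetia*
record, revised *Primula matthioli* authorship, *Carex binervis*
chresonym, the *Rosa inodora*/*R. elliptica* synonym concept, and the
*Ammophila* hemihomonym). Identifiers the sources do not print are
synthetic stand-ins from a reserved 1000xxx range, marked as such in
the fixture's docstring.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fuzzy_threshold` | 1 | max edit distance for a fuzzy match (characters) |
| `root_taxon_id` | 33090 | NCBI subtree supplying reference names (Viridiplantae) |
| `MAX_CHAIN_HOPS` | 10 | accepted-id chain cap; longer chains are reported as cycles (real chains are ≤ 2) |
| SPARQL batch size | 1000 | identifiers per VALUES block |
| `retrieved` | — | P813 reference date, required input |
| world `n_species` | 100 | checklist size of a generated world |
| pathology rates | 0 | fraction of species per pathology; must sum to ≤ 1 |

## Numerical and degenerate-input choices

All file formats are UTF-8; undecodable bytes are replaced and logged.
Unknown taxonomic status strings map to `doubtful` with a warning
(kept, never silently treated as accepted); unknown ranks map to
`other`. Dangling accepted-id pointers are flagged, not dropped.
Accepted-id cycles raise a resolution error naming the cycle. All
iteration orders are insertion orders and all tie-breaks are on
identifiers, so every writer is byte-deterministic; the only random
source is the world generator's seeded RNG.

Test and acceptance problem sizes — 50×50 oracle comparisons,
1000-item snapshots, 1000-species clean worlds, 300-species planted
worlds — were chosen as the smallest sizes at which every pathology
occurs many times and index/scan code paths diverge from trivial ones.

## Known limitations

* The name parser covers the syntax exercised by European vascular
  plant checklists; full nomenclator-grade parsing (nothonames below
  genus, "non …"/"auct." annotations, cultivar epithets) is out of
  scope.
* Author normalisation is a convention table, not an author authority
  file; two different botanists sharing a surname abbreviation will
  compare equal.
* Genus-only (`partial_exact`) candidates are never used for linking,
  even when the species epithet differs only by gender agreement
  beyond the stem-fold set.
* The Wikidata snapshot is flat: one row per claim value, no
  qualifiers except the P846 rank, no item merging history.
* Live SPARQL execution and Wikidata write access are deliberately
  absent; the package generates queries and edit batches but never
  talks to the network.
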