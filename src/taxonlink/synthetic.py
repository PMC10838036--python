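"""Synthetic test worlds: a coherent GBIF backbone + species-list
checklist + NCBI taxdump + Wikidata snapshot, with pathologies planted
at configured rates and a ground-truth table of expected outcomes.

Each pathology emulates one failure mode seen in real identifier
linking:

``stale_gbif_link``
    Wikidata still carries a GBIF id that was deleted from the Backbone
    (batch-update case, action e).
``merged_ncbi``
    Wikidata carries an NCBI id that was since merged into another
    (verify-and-update case, action c).
``homonym``
    The NCBI name is an identically spelled name with a different
    author and Wikidata has no NCBI link to arbitrate (action h).
``chresonym``
    The NCBI record cites a later *usage* of the name, so its author
    differs although the identifiers agree (action g).
``missing_author``
    The NCBI record has no authority string (action g... action g is
    the noauthor verification queue).
``misspelling``
    The NCBI spelling is one edit away (fuzzy match, manual queue).
``synonym_pair``
    The taxon has a different accepted name in NCBI, reachable only
    through a GBIF synonym (synonym-verification queue, action f).
``hemihomonym``
    An identically named taxon exists in another kingdom's subtree of
    the NCBI tree; the subtree restriction must keep it out of the
    reference set, so the case still auto-accepts.

Distinct species names are kept at pairwise edit distance ≥ 3, so a
planted distance-1 misspelling is unambiguous.  Worlds are byte-identical
under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import edlib

from .io_formats import (
    TaxonStore,
    write_gbif_backbone,
    write_ncbi_taxdump,
    write_species_list,
)
from .records import ChecklistEntry, Rank, SourceDb, Status, TaxonRecord
from .triage import Action
from .wikidata import WikidataSnapshot, WikidataTaxonItem

__all__ = ["WorldConfig", "TruthRecord", "World", "generate_world", "paper_fixture_world", "write_world"]

#: node ids of the synthetic NCBI tree
NCBI_ROOT = "1"
NCBI_PLANTS = "33090"  # green plants
NCBI_ANIMALS = "33208"  # metazoa

_PATHOLOGIES = (
    "homonym",
    "hemihomonym",
    "synonym_pair",
    "missing_author",
    "misspelling",
    "stale_gbif_link",
    "merged_ncbi",
    "chresonym",
)

_AUTHORS = (
    "L.", "Sm.", "Mill.", "Lam.", "DC.", "Fr.", "Tausch", "Host", "Roxb.",
    "Schrad.", "Willd.", "Hultén", "Hook.f.", "A.Gray", "Benth.", "Rchb.",
    "Boiss.", "Trin.", "Nees", "Koeler",
)

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ru",
    "sa", "te", "vi", "xo", "zu", "ca", "del", "fir", "gon", "har",
)


@dataclass
class WorldConfig:
    n_species: int = 100
    rate_homonym: float = 0.0
    rate_hemihomonym: float = 0.0
    rate_synonym_pair: float = 0.0
    rate_missing_author: float = 0.0
    rate_misspelling: float = 0.0
    rate_stale_gbif_link: float = 0.0
    rate_merged_ncbi: float = 0.0
    rate_chresonym: float = 0.0
    seed: int = 0

    def rates(self) -> dict[str, float]:
        return {name: getattr(self, "rate_" + name) for name in _PATHOLOGIES}

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        for name, rate in self.rates().items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate_{name} outside [0, 1]")
        if sum(self.rates().values()) > 1.0 + 1e-9:
            raise ValueError("pathology rates sum to more than 1 (one pathology per species)")


@dataclass
class TruthRecord:
    gbif_id: str
    ncbi_id: str  # empty when the species has no NCBI record
    expected_action: Action | None  # None when the entry is filtered out pre-triage
    planted_pathology: str  # "clean" or one of the pathology names


@dataclass
class World:
    backbone: TaxonStore
    species_list: list[ChecklistEntry]
    ncbi: TaxonStore
    snapshot: WikidataSnapshot
    truth: list[TruthRecord]
    plant_root: str = NCBI_PLANTS


class _NameForge:
    """Latin-flavoured name generator keeping pairwise distance ≥ 3."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.canonicals: list[str] = []

    def _word(self, n_syllables: int) -> str:
        return "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables))

    def species(self) -> str:
        for _ in range(10_000):
            genus = self._word(3).capitalize()
            epithet = self._word(3) + self.rng.choice(("us", "a", "um", "is", "ii"))
            canonical = f"{genus} {epithet}"
            if all(
                edlib.align(canonical, other, task="distance", k=2)["editDistance"] == -1
                for other in self.canonicals
            ):
                self.canonicals.append(canonical)
                return canonical
        raise RuntimeError("name generator exhausted (too many species for the syllable space)")


def _higher_plantae() -> list[tuple[str, str, str]]:
    return [("kingdom", "Plantae", "6")]


def _add_tree_scaffold(ncbi: TaxonStore) -> None:
    """Root, plant and animal nodes of the synthetic NCBI tree."""
    from .name_parsing import parse_name

    for node_id, name, parent in (
        (NCBI_ROOT, "root", NCBI_ROOT),
        (NCBI_PLANTS, "Viridiplantae", NCBI_ROOT),
        (NCBI_ANIMALS, "Metazoa", NCBI_ROOT),
    ):
        ncbi.add(
            TaxonRecord(
                source_db=SourceDb.NCBI,
                taxon_id=node_id,
                scientific_name=name,
                canonical_name=parse_name(name).canonical,
                rank=Rank.OTHER,
                parent_id="" if node_id == parent else parent,
            )
        )


def generate_world(config: WorldConfig) -> World:
    """Build a world according to ``config``; deterministic under seed."""
    config.validate()
    rng = random.Random(config.seed)
    forge = _NameForge(rng)
    n = config.n_species

    assignments = ["clean"] * n
    indices = list(range(n))
    rng.shuffle(indices)
    cursor = 0
    planted_counts = {}
    for name, rate in config.rates().items():
        count = int(round(rate * n))
        planted_counts[name] = count
        for idx in indices[cursor : cursor + count]:
            assignments[idx] = name
        cursor += count

    backbone = TaxonStore(SourceDb.GBIF)
    ncbi = TaxonStore(SourceDb.NCBI)
    snapshot_items: list[WikidataTaxonItem] = []
    species_list: list[ChecklistEntry] = []
    truth: list[TruthRecord] = []

    _add_tree_scaffold(ncbi)

    next_gbif = 5_000_000
    next_ncbi = 100_000
    next_qid = 20_000_000
    next_stale = 3_000_000

    def new_gbif() -> str:
        nonlocal next_gbif
        next_gbif += 1
        return str(next_gbif)

    def new_ncbi() -> str:
        nonlocal next_ncbi
        next_ncbi += 1
        return str(next_ncbi)

    def new_qid() -> str:
        nonlocal next_qid
        next_qid += 1
        return f"Q{next_qid}"

    for pathology in assignments:
        canonical = forge.species()
        author = rng.choice(_AUTHORS)
        other_author = rng.choice([a for a in _AUTHORS if a != author])
        gbif_id = new_gbif()
        ncbi_id = new_ncbi()
        qid = new_qid()

        gbif_name = f"{canonical} {author}"
        backbone.add(
            TaxonRecord(
                source_db=SourceDb.GBIF,
                taxon_id=gbif_id,
                scientific_name=gbif_name,
                canonical_name=canonical,
                authorship=author,
                rank=Rank.SPECIES,
                status=Status.ACCEPTED,
            )
        )
        species_list.append(
            ChecklistEntry(
                supplied_name=gbif_name,
                gbif_taxon_id=gbif_id,
                status_at_import=Status.ACCEPTED,
                rank=Rank.SPECIES,
                higher_taxa=_higher_plantae(),
            )
        )

        ncbi_canonical = canonical
        ncbi_author: str | None = author
        item = WikidataTaxonItem(
            qid=qid, taxon_name=canonical, taxon_author=author, gbif_id=gbif_id, ncbi_id=ncbi_id
        )
        expected = Action.B_AUTO_ACCEPT

        if pathology == "homonym":
            # same spelling, different author; Wikidata has no NCBI link
            ncbi_author = other_author
            item.ncbi_id = ""
            expected = Action.H_POSSIBLE_HOMONYM
        elif pathology == "chresonym":
            # author cites a later usage; identifiers themselves agree
            ncbi_author = other_author
            expected = Action.G_VERIFY_AUTHORSHIP
        elif pathology == "missing_author":
            ncbi_author = None
            expected = Action.G_VERIFY_AUTHORSHIP
        elif pathology == "misspelling":
            chars = list(canonical)
            pos = rng.randrange(len(canonical.split()[0]) + 1, len(chars))
            alphabet = [c for c in "abcdefghijklmnopqrstuvz" if c != chars[pos]]
            chars[pos] = rng.choice(alphabet)
            ncbi_canonical = "".join(chars)
            expected = Action.OTHER
        elif pathology == "stale_gbif_link":
            next_stale += 1
            item.gbif_id = str(next_stale)
            expected = Action.E_BATCH_UPDATE_GBIF
        elif pathology == "merged_ncbi":
            old_id = new_ncbi()
            ncbi.add(
                TaxonRecord(
                    source_db=SourceDb.NCBI,
                    taxon_id=old_id,
                    scientific_name="",
                    status=Status.MERGED,
                    accepted_id=ncbi_id,
                )
            )
            item.ncbi_id = old_id
            expected = Action.C_VERIFY_UPDATE_NCBI
        elif pathology == "synonym_pair":
            # different accepted name in NCBI, reachable via a GBIF synonym
            synonym_canonical = forge.species()
            synonym_id = new_gbif()
            backbone.add(
                TaxonRecord(
                    source_db=SourceDb.GBIF,
                    taxon_id=synonym_id,
                    scientific_name=f"{synonym_canonical} {other_author}",
                    canonical_name=synonym_canonical,
                    authorship=other_author,
                    rank=Rank.SPECIES,
                    status=Status.SYNONYM,
                    accepted_id=gbif_id,
                )
            )
            ncbi_canonical = synonym_canonical
            ncbi_author = other_author
            item.gbif_id = synonym_id
            item.taxon_name = synonym_canonical
            item.taxon_author = other_author
            expected = Action.F_VERIFY_SYNONYM
        elif pathology == "hemihomonym":
            # out-of-kingdom twin; must not disturb the in-subtree match
            twin_id = new_ncbi()
            ncbi.add(
                TaxonRecord(
                    source_db=SourceDb.NCBI,
                    taxon_id=twin_id,
                    scientific_name=ncbi_canonical,
                    canonical_name=ncbi_canonical,
                    authorship=other_author,
                    rank=Rank.SPECIES,
                    parent_id=NCBI_ANIMALS,
                )
            )

        ncbi.add(
            TaxonRecord(
                source_db=SourceDb.NCBI,
                taxon_id=ncbi_id,
                scientific_name=ncbi_canonical,
                canonical_name=ncbi_canonical,
                authorship=ncbi_author or "",
                rank=Rank.SPECIES,
                parent_id=NCBI_PLANTS,
            )
        )
        snapshot_items.append(item)
        truth.append(TruthRecord(gbif_id, ncbi_id, expected, pathology))

    return World(
        backbone=backbone,
        species_list=species_list,
        ncbi=ncbi,
        snapshot=WikidataSnapshot(snapshot_items),
        truth=truth,
    )


def write_world(world: World, directory: str | Path) -> None:
    """Serialise a world in the exact on-disk dialects of the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_species_list(world.species_list, directory / "species_list.tsv")
    write_gbif_backbone(world.backbone, directory / "backbone.tsv")
    write_ncbi_taxdump(world.ncbi, directory / "taxdump")
    world.snapshot.write(directory / "wikidata.tsv")
    lines = ["\t".join(("gbif_id", "ncbi_id", "expected_action", "planted_pathology"))]
    for record in world.truth:
        lines.append(
            "\t".join(
                (
                    record.gbif_id,
                    record.ncbi_id,
                    record.expected_action.value if record.expected_action else "",
                    record.planted_pathology,
                )
            )
        )
    (directory / "truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fixture_record(store: TaxonStore, taxon_id: str, name: str, rank: Rank,
                    status: Status, accepted_id: str = "", parent_id: str = "") -> None:
    from .name_parsing import parse_name

    parsed = parse_name(name)
    store.add(
        TaxonRecord(
            source_db=store.source_db,
            taxon_id=taxon_id,
            scientific_name=name,
            canonical_name=parsed.canonical,
            authorship=parsed.authorship_verbatim,
            rank=rank,
            status=status,
            accepted_id=accepted_id,
            parent_id=parent_id,
        )
    )


def paper_fixture_world() -> World:
    """Fixed fixture world encoding eight documented curation cases with
    their published identifiers.

    Identifiers that the source records do not print (some NCBI taxids
    and one GBIF id) are synthetic stand-ins drawn from a reserved
    1000xxx range.  The cases:

    * *Helianthus annuus*: Wikidata item Q171497 holds the deleted GBIF
      id 3119195; the accepted record is 9206251 → batch-update (e).
    * *Calamagrostis stricta*: NCBI id 497295 merged into 395286, while
      GBIF and NCBI disagree about the accepted name → manual (other).
    * *Rubus gracilis* C.Presl & J.S.Presl vs the homonym *R. gracilis*
      Roxb. linked on Q17248013 → author-mismatch homonym flag.
    * *Willemetia stipitata*: GBIF 5389300 is doubtful → filtered out.
    * *Primula matthioli*: record 9764749 "(L.) V.A.Richt." is now
      accepted, the checklist's 5640570 "K.Richt." a homotypic synonym
      → resolves and auto-accepts (b).
    * *Carex binervis* Sm. vs the NCBI chresonym "Gren. & Godr."
      (txid372257) → authorship verification (g).
    * *Rosa inodora* Fr. (3002258, Q15844731) matches NCBI only through
      its GBIF synonym *Rosa elliptica* Tausch (3003248, Q9325795,
      txid323240) → synonym verification (f).
    * the *Ammophila* hemihomonym: wasp genus (1346141, Kirby, 1798) vs
      grass genus (2703794, Host), both genus rank → dropped by the
      species filter.
    """
    backbone = TaxonStore(SourceDb.GBIF)
    ncbi = TaxonStore(SourceDb.NCBI)
    entries: list[ChecklistEntry] = []
    items: list[WikidataTaxonItem] = []
    truth: list[TruthRecord] = []

    _add_tree_scaffold(ncbi)

    def entry(name: str, gbif_id: str, rank=Rank.SPECIES, status=Status.ACCEPTED,
              kingdom: str = "Plantae") -> None:
        entries.append(
            ChecklistEntry(
                supplied_name=name,
                gbif_taxon_id=gbif_id,
                status_at_import=status,
                rank=rank,
                higher_taxa=[("kingdom", kingdom, "")],
            )
        )

    def ncbi_species(taxon_id: str, canonical: str, authority: str = "") -> None:
        ncbi.add(
            TaxonRecord(
                source_db=SourceDb.NCBI,
                taxon_id=taxon_id,
                scientific_name=canonical,
                canonical_name=canonical,
                authorship=authority,
                rank=Rank.SPECIES,
                parent_id=NCBI_PLANTS,
            )
        )

    # 1 — Helianthus annuus (stale GBIF id on Wikidata); txid is synthetic
    _fixture_record(backbone, "9206251", "Helianthus annuus L.", Rank.SPECIES, Status.ACCEPTED)
    entry("Helianthus annuus L.", "9206251")
    ncbi_species("1000011", "Helianthus annuus", "L.")
    items.append(WikidataTaxonItem("Q171497", "Helianthus annuus", "L.", "3119195", "1000011"))
    truth.append(TruthRecord("9206251", "1000011", Action.E_BATCH_UPDATE_GBIF, "stale_gbif_link"))

    # 2 — Calamagrostis stricta (merged NCBI id; accepted names disagree);
    #     the Wikidata QID is a synthetic stand-in
    _fixture_record(backbone, "2704899", "Calamagrostis stricta (Timm) Koeler", Rank.SPECIES, Status.ACCEPTED)
    _fixture_record(backbone, "4104731", "Calamagrostis neglecta (Ehrh.) G.Gaertn.", Rank.SPECIES, Status.SYNONYM, accepted_id="4142326")
    _fixture_record(backbone, "4142326", "Achnatherum calamagrostis (L.) P.Beauv.", Rank.SPECIES, Status.ACCEPTED)
    entry("Calamagrostis stricta (Timm) Koeler", "2704899")
    ncbi_species("395286", "Calamagrostis neglecta", "(Ehrh.) G.Gaertn.")
    ncbi.add(
        TaxonRecord(
            source_db=SourceDb.NCBI,
            taxon_id="497295",
            scientific_name="",
            status=Status.MERGED,
            accepted_id="395286",
        )
    )
    items.append(WikidataTaxonItem("Q91000002", "Calamagrostis stricta", "(Timm) Koeler", "2704899", "497295"))
    truth.append(TruthRecord("2704899", "", Action.OTHER, "merged_ncbi"))

    # 3 — Rubus gracilis homonym pair; the checklist record's GBIF id and
    #     the NCBI txid are synthetic stand-ins
    _fixture_record(backbone, "1000031", "Rubus gracilis C.Presl & J.S.Presl", Rank.SPECIES, Status.ACCEPTED)
    _fixture_record(backbone, "2990660", "Rubus gracilis Roxb.", Rank.SPECIES, Status.ACCEPTED)
    entry("Rubus gracilis C.Presl & J.S.Presl", "1000031")
    ncbi_species("1000032", "Rubus gracilis", "Roxb.")
    items.append(WikidataTaxonItem("Q17248013", "Rubus gracilis", "C.Presl & J.S.Presl", "2990660", "1000032"))
    truth.append(TruthRecord("1000031", "1000032", Action.OTHER, "homonym"))

    # 4 — Willemetia stipitata: doubtful in GBIF, filtered out
    _fixture_record(backbone, "5389300", "Willemetia stipitata (Jacq.) Dalla Torre", Rank.SPECIES, Status.DOUBTFUL)
    entry("Willemetia stipitata (Jacq.) Dalla Torre", "5389300", status=Status.DOUBTFUL)
    ncbi_species("519273", "Willemetia stipitata", "Cass.")
    items.append(WikidataTaxonItem("Q1362051", "Willemetia stipitata", "Dalla Torre", "5389300", "519273"))
    truth.append(TruthRecord("5389300", "", None, "doubtful_dropped"))

    # 5 — Primula matthioli: checklist id is a homotypic synonym of the
    #     now-accepted 9764749; txid synthetic
    _fixture_record(backbone, "9764749", "Primula matthioli (L.) V.A.Richt.", Rank.SPECIES, Status.ACCEPTED)
    _fixture_record(backbone, "5640570", "Primula matthioli K.Richt.", Rank.SPECIES, Status.SYNONYM, accepted_id="9764749")
    _fixture_record(backbone, "9781637", "Primula matthioli (L.) J.A.Richt.", Rank.SPECIES, Status.SYNONYM, accepted_id="9764749")
    entry("Primula matthioli K.Richt.", "5640570", status=Status.SYNONYM)
    ncbi_species("1000061", "Primula matthioli", "(L.) V.A.Richt.")
    items.append(WikidataTaxonItem("Q50859720", "Primula matthioli", "(L.) V.A.Richt.", "9764749", "1000061"))
    truth.append(TruthRecord("5640570", "1000061", Action.B_AUTO_ACCEPT, "updated_backbone"))

    # 6 — Carex binervis: NCBI author string is a chresonym
    _fixture_record(backbone, "2723521", "Carex binervis Sm.", Rank.SPECIES, Status.ACCEPTED)
    entry("Carex binervis Sm.", "2723521")
    ncbi_species("372257", "Carex binervis", "Gren. & Godr.")
    items.append(WikidataTaxonItem("Q160245", "Carex binervis", "Sm.", "2723521", "372257"))
    truth.append(TruthRecord("2723521", "372257", Action.G_VERIFY_AUTHORSHIP, "chresonym"))

    # 7 — Rosa inodora: NCBI reachable only via the GBIF synonym Rosa elliptica
    _fixture_record(backbone, "3002258", "Rosa inodora Fr.", Rank.SPECIES, Status.ACCEPTED)
    _fixture_record(backbone, "3003248", "Rosa elliptica Tausch", Rank.SPECIES, Status.SYNONYM, accepted_id="3002258")
    entry("Rosa inodora Fr.", "3002258")
    ncbi_species("323240", "Rosa elliptica", "Tausch")
    items.append(WikidataTaxonItem("Q15844731", "Rosa inodora", "Fr.", "3002258", ""))
    items.append(WikidataTaxonItem("Q9325795", "Rosa elliptica", "Tausch", "3003248", "323240"))
    truth.append(TruthRecord("3002258", "323240", Action.F_VERIFY_SYNONYM, "synonym_pair"))

    # 8 — Ammophila hemihomonym: wasp genus imported in place of the grass
    _fixture_record(backbone, "1346141", "Ammophila Kirby, 1798", Rank.GENUS, Status.ACCEPTED)
    _fixture_record(backbone, "2703794", "Ammophila Host", Rank.GENUS, Status.ACCEPTED)
    entry("Ammophila Kirby, 1798", "1346141", rank=Rank.GENUS, kingdom="Animalia")
    truth.append(TruthRecord("1346141", "", None, "hemihomonym"))

    return World(
        backbone=backbone,
        species_list=entries,
        ncbi=ncbi,
        snapshot=WikidataSnapshot(items),
        truth=truth,
    )
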