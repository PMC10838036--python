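"""Curation-action triage: the outcome-table rules, homonym flags and
summary counts."""

import itertools
import random

import pytest

from taxonlink.matching import AuthorClass, MatchCategory, NameMatch, classify_match_authors
from taxonlink.records import ChecklistEntry, Rank, SourceDb, Status, TaxonRecord
from taxonlink.triage import (
    Action,
    HomonymKind,
    assemble_case,
    flag_homonyms,
    summarize,
    triage_case,
)
from taxonlink.wikidata import LinkEvidence, WikidataTaxonItem


def _record(taxon_id, canonical="Carex binervis", author="Sm.", db=SourceDb.NCBI, authorships=None):
    return TaxonRecord(
        source_db=db,
        taxon_id=taxon_id,
        scientific_name=f"{canonical} {author}".strip(),
        canonical_name=canonical,
        authorship=author,
        rank=Rank.SPECIES,
        authorships=tuple(authorships) if authorships is not None else (),
    )


def _match(mtype, via_synonym=""):
    """A best-match carrying the given outcome-table match type."""
    if mtype == "none":
        return None
    category = MatchCategory.FUZZY if mtype == "fuzzy" else MatchCategory.EXACT
    author_class = {
        "exact": AuthorClass.EXACT,
        "noauthor": AuthorClass.NOAUTHOR,
        "author_mismatch": AuthorClass.AUTHOR_MISMATCH,
        "fuzzy": AuthorClass.EXACT,
    }[mtype]
    return NameMatch(
        query=_record("G1", db=SourceDb.GBIF),
        reference=_record("N1"),
        category=category,
        author_class=author_class,
        edit_distance=1 if mtype == "fuzzy" else 0,
        via_synonym=via_synonym,
    )


_ITEM = WikidataTaxonItem("Q1", gbif_id="G1", ncbi_id="N1")


def _evidence(kind):
    if kind == "forward_same":
        return LinkEvidence(gbif_linked=True, wd_ncbi_id="N1", forward_item=_ITEM)
    if kind == "forward_diff":
        return LinkEvidence(gbif_linked=True, wd_ncbi_id="N2", forward_item=_ITEM)
    if kind == "forward_no_ncbi":
        return LinkEvidence(gbif_linked=True, wd_ncbi_id="", forward_item=_ITEM)
    if kind == "reverse":
        return LinkEvidence(gbif_linked=False, reverse_item=_ITEM)
    return LinkEvidence()


class TestOutcomeTableRows:
    """The printed rows of the curation-outcome table, one per case."""

    @pytest.mark.parametrize(
        "mtype, evidence_kind, status, action",
        [
            ("none", "none", Status.ACCEPTED, Action.A_NO_MATCH),
            ("none", "reverse", Status.ACCEPTED, Action.OTHER),
            ("exact", "forward_same", Status.ACCEPTED, Action.B_AUTO_ACCEPT),
            ("exact", "forward_diff", Status.ACCEPTED, Action.C_VERIFY_UPDATE_NCBI),
            ("exact", "forward_no_ncbi", Status.ACCEPTED, Action.D_BATCH_ADD_NCBI),
            ("exact", "reverse", Status.ACCEPTED, Action.E_BATCH_UPDATE_GBIF),
            ("exact", "reverse", Status.SYNONYM, Action.F_VERIFY_SYNONYM),
            ("noauthor", "forward_same", Status.ACCEPTED, Action.G_VERIFY_AUTHORSHIP),
            ("noauthor", "forward_diff", Status.ACCEPTED, Action.H_POSSIBLE_HOMONYM),
            ("noauthor", "forward_no_ncbi", Status.ACCEPTED, Action.H_POSSIBLE_HOMONYM),
            ("author_mismatch", "forward_same", Status.ACCEPTED, Action.G_VERIFY_AUTHORSHIP),
            ("author_mismatch", "forward_diff", Status.ACCEPTED, Action.H_POSSIBLE_HOMONYM),
            ("author_mismatch", "forward_no_ncbi", Status.ACCEPTED, Action.H_POSSIBLE_HOMONYM),
            ("fuzzy", "forward_same", Status.ACCEPTED, Action.OTHER),
            ("fuzzy", "none", Status.SYNONYM, Action.OTHER),
        ],
    )
    def test_row_maps_to_lettered_action(self, mtype, evidence_kind, status, action):
        assert triage_case(_match(mtype), _evidence(evidence_kind), status) is action

    def test_exhaustive_domain_is_total_and_deterministic(self):
        """Every combination of the finite input space yields exactly one
        action, twice over."""
        mtypes = ("none", "exact", "noauthor", "author_mismatch", "fuzzy")
        evidence_kinds = ("none", "forward_same", "forward_diff", "forward_no_ncbi", "reverse")
        statuses = (Status.ACCEPTED, Status.SYNONYM, Status.DOUBTFUL)
        via = ("", "S1")
        seen = 0
        for mtype, kind, status, syn in itertools.product(mtypes, evidence_kinds, statuses, via):
            match = _match(mtype, via_synonym=syn)
            first = triage_case(match, _evidence(kind), status)
            second = triage_case(_match(mtype, via_synonym=syn), _evidence(kind), status)
            assert isinstance(first, Action)
            assert first is second
            seen += 1
        assert seen == len(mtypes) * len(evidence_kinds) * len(statuses) * len(via)

    @pytest.mark.parametrize(
        "evidence_kind, plain_action",
        [
            ("forward_same", Action.B_AUTO_ACCEPT),
            ("forward_no_ncbi", Action.D_BATCH_ADD_NCBI),
            ("reverse", Action.E_BATCH_UPDATE_GBIF),
        ],
    )
    def test_via_synonym_demotes_automatic_actions(self, evidence_kind, plain_action):
        assert triage_case(_match("exact"), _evidence(evidence_kind), Status.ACCEPTED) is plain_action
        demoted = triage_case(_match("exact", via_synonym="S1"), _evidence(evidence_kind), Status.ACCEPTED)
        assert demoted is Action.F_VERIFY_SYNONYM


def _entry(gbif_id="G1", kingdom="Plantae"):
    return ChecklistEntry(
        supplied_name="Carex binervis Sm.",
        gbif_taxon_id=gbif_id,
        rank=Rank.SPECIES,
        higher_taxa=[("kingdom", kingdom, "")],
    )


class TestAssembleCase:
    def test_exact_tie_between_candidates_goes_to_manual(self):
        first = _match("exact")
        second = _match("exact")
        second.reference = _record("N2")
        case = assemble_case(_entry(), [first, second], _evidence("forward_same"), Status.ACCEPTED)
        assert case.action is Action.OTHER

    def test_ranked_winner_used_when_no_tie(self):
        good = _match("exact")
        worse = _match("author_mismatch")
        worse.reference = _record("N2", author="Roxb.")
        case = assemble_case(_entry(), [worse, good], _evidence("forward_same"), Status.ACCEPTED)
        assert case.best_match is good
        assert case.action is Action.B_AUTO_ACCEPT
        assert case.ncbi_agrees_with_wikidata.value == "yes"


class TestFlagHomonyms:
    def _case(self, query_author, ref_author, query_kingdom, ref_kingdom):
        match = NameMatch(
            query=_record("G1", canonical="Ammophila", author=query_author, db=SourceDb.GBIF),
            reference=_record("N1", canonical="Ammophila", author=ref_author, authorships=[ref_author]),
            category=MatchCategory.EXACT,
        )
        classify_match_authors(match)
        case = assemble_case(
            _entry(kingdom=query_kingdom), [match], _evidence("forward_same"), Status.ACCEPTED,
            reference_kingdom=ref_kingdom,
        )
        return case

    def test_cross_kingdom_conflict_is_hemihomonym(self):
        # the wasp genus Ammophila Kirby, 1798 vs the grass genus Ammophila Host
        case = self._case("Kirby, 1798", "Host", "Animalia", "Plantae")
        [flag] = flag_homonyms([case])
        assert flag.kind is HomonymKind.HEMIHOMONYM
        assert flag.conflicting_authors[0] != flag.conflicting_authors[1]

    def test_same_kingdom_conflict_is_within_code(self):
        case = self._case("C.Presl & J.S.Presl", "Roxb.", "Plantae", "Plantae")
        [flag] = flag_homonyms([case])
        assert flag.kind is HomonymKind.WITHIN_CODE

    def test_orthographic_variants_never_flagged(self):
        case = self._case("Hook.f.", "Hook.fil.", "Plantae", "Plantae")
        assert flag_homonyms([case]) == []
        case = self._case("Hultén", "Hulten", "Plantae", "Plantae")
        assert flag_homonyms([case]) == []

    def test_clean_world_has_zero_flags(self, clean_world):
        from taxonlink.pipeline import run_linking

        result = run_linking(
            clean_world.species_list,
            clean_world.backbone,
            clean_world.ncbi,
            clean_world.snapshot,
            reference_kingdom="Plantae",
        )
        assert result.flags == []

    def test_planted_homonyms_all_flagged(self, planted_world):
        from taxonlink.pipeline import run_linking

        result = run_linking(
            planted_world.species_list,
            planted_world.backbone,
            planted_world.ncbi,
            planted_world.snapshot,
            reference_kingdom="Plantae",
        )
        flagged = {f.case.entry.gbif_taxon_id for f in result.flags}
        homonyms = {
            t.gbif_id for t in planted_world.truth if t.planted_pathology == "homonym"
        }
        assert homonyms <= flagged


class TestSummarize:
    def test_empty_input_all_zero(self):
        counts = summarize([])
        assert set(counts) == set(Action)
        assert all(v == 0 for v in counts.values())

    def test_counts_conserve_and_ignore_order(self, planted_world):
        from taxonlink.pipeline import run_linking

        result = run_linking(
            planted_world.species_list,
            planted_world.backbone,
            planted_world.ncbi,
            planted_world.snapshot,
            reference_kingdom="Plantae",
        )
        counts = summarize(result.cases)
        assert sum(counts.values()) == len(result.cases)
        shuffled = list(result.cases)
        random.Random(0).shuffle(shuffled)
        assert summarize(shuffled) == counts

    def test_counts_equal_generator_quotas(self, planted_world):
        from taxonlink.pipeline import run_linking

        result = run_linking(
            planted_world.species_list,
            planted_world.backbone,
            planted_world.ncbi,
            planted_world.snapshot,
            reference_kingdom="Plantae",
        )
        counts = summarize(result.cases)
        expected = {action: 0 for action in Action}
        for truth in planted_world.truth:
            if truth.expected_action is not None:
                expected[truth.expected_action] += 1
        assert counts == expected
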