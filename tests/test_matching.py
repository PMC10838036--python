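"""Name matching, author refinement and the synonym second round."""

from taxonlink.matching import (
    AuthorClass,
    MatchCategory,
    NameMatch,
    classify_match_authors,
    match_names,
    second_round_via_synonyms,
)
from taxonlink.records import Rank, SourceDb, Status, TaxonRecord
from taxonlink.io_formats import TaxonStore
from taxonlink.synthetic import WorldConfig, generate_world


def _record(taxon_id, canonical, author="", db=SourceDb.GBIF, authorships=None):
    return TaxonRecord(
        source_db=db,
        taxon_id=taxon_id,
        scientific_name=f"{canonical} {author}".strip(),
        canonical_name=canonical,
        authorship=author,
        rank=Rank.SPECIES,
        authorships=tuple(authorships) if authorships is not None else (),
    )


def _levenshtein(a, b):
    """Textbook DP edit distance, independent of the matcher's library."""
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        current = [i]
        for j, cb in enumerate(b, 1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[-1]


class TestMatchNames:
    def test_equal_canonicals_are_exact_distance_zero(self):
        [match] = [
            m
            for m in match_names([_record("q", "Carex binervis")], [_record("r", "Carex binervis", db=SourceDb.NCBI)])
        ]
        assert match.category is MatchCategory.EXACT
        assert match.edit_distance == 0

    def test_matching_is_case_insensitive(self):
        [match] = match_names(
            [_record("q", "Carex Binervis")], [_record("r", "carex binervis", db=SourceDb.NCBI)]
        )
        assert match.category is MatchCategory.EXACT

    def test_one_edit_misspelling_is_fuzzy(self):
        [match] = match_names(
            [_record("q", "Carex binervis")], [_record("r", "Carex binervjs", db=SourceDb.NCBI)]
        )
        assert match.category is MatchCategory.FUZZY
        assert match.edit_distance == 1

    def test_gender_stem_fold_is_fuzzy(self):
        [match] = match_names(
            [_record("q", "Pilosella breva")], [_record("r", "Pilosella brevum", db=SourceDb.NCBI)]
        )
        assert match.category is MatchCategory.FUZZY
        assert match.stem_fold
        assert match.edit_distance > 0

    def test_genus_only_agreement_is_partial_and_excluded(self):
        [match] = match_names(
            [_record("q", "Carex binervis")], [_record("r", "Carex pulicaris", db=SourceDb.NCBI)]
        )
        assert match.category is MatchCategory.PARTIAL_EXACT
        assert match.excluded

    def test_no_candidates_yields_none_record(self):
        [match] = match_names(
            [_record("q", "Carex binervis")], [_record("r", "Poa annua", db=SourceDb.NCBI)]
        )
        assert match.category is MatchCategory.NONE
        assert match.reference is None

    def test_output_partitions_queries(self, planted_world):
        queries = [r for r in planted_world.backbone if r.status is Status.ACCEPTED]
        references = [
            r for r in planted_world.ncbi if r.rank is Rank.SPECIES and r.status is Status.ACCEPTED
        ]
        matches = match_names(queries, references)
        assert {m.query.taxon_id for m in matches} == {q.taxon_id for q in queries}

    def test_agrees_with_exhaustive_pairwise_oracle(self):
        """All-pairs result on a 50x50 set equals a brute-force DP scan."""
        world = generate_world(WorldConfig(n_species=50, seed=5, rate_misspelling=0.2))
        queries = [r for r in world.backbone if r.status is Status.ACCEPTED]
        references = [
            r for r in world.ncbi if r.rank is Rank.SPECIES and r.status is Status.ACCEPTED
        ]
        assert len(queries) == 50 and len(references) >= 50
        threshold = 1
        expected = set()
        for q in queries:
            for r in references:
                d = _levenshtein(q.canonical_name.casefold(), r.canonical_name.casefold())
                if d <= threshold:
                    expected.add((q.taxon_id, r.taxon_id, "exact" if d == 0 else "fuzzy"))
        got = {
            (m.query.taxon_id, m.reference.taxon_id, m.category.value)
            for m in match_names(queries, references, threshold)
            if m.category in (MatchCategory.EXACT, MatchCategory.FUZZY) and not m.stem_fold
        }
        assert got == expected

    def test_raising_threshold_never_loses_matches(self):
        world = generate_world(WorldConfig(n_species=40, seed=9, rate_misspelling=0.3))
        queries = [r for r in world.backbone if r.status is Status.ACCEPTED]
        references = [
            r for r in world.ncbi if r.rank is Rank.SPECIES and r.status is Status.ACCEPTED
        ]

        def matched(threshold):
            return {
                m.query.taxon_id
                for m in match_names(queries, references, threshold)
                if m.category in (MatchCategory.EXACT, MatchCategory.FUZZY)
            }

        previous = set()
        for threshold in (0, 1, 2, 3):
            current = matched(threshold)
            assert previous <= current
            previous = current


class TestClassifyAuthors:
    def _classified(self, q_author, ref_authorships):
        match = NameMatch(
            query=_record("q", "Carex binervis", q_author),
            reference=_record("r", "Carex binervis", db=SourceDb.NCBI, authorships=ref_authorships),
            category=MatchCategory.EXACT,
        )
        return classify_match_authors(match)

    def test_identical_authors_exact(self):
        assert self._classified("Sm.", ["Sm."]).author_class is AuthorClass.EXACT

    def test_missing_reference_authority_noauthor(self):
        assert self._classified("Sm.", []).author_class is AuthorClass.NOAUTHOR

    def test_conflicting_authors_mismatch(self):
        match = self._classified("C.Presl & J.S.Presl", ["Roxb."])
        assert match.author_class is AuthorClass.AUTHOR_MISMATCH

    def test_any_of_several_authorities_may_match(self):
        match = self._classified("Sm.", ["Gren. & Godr.", "Sm."])
        assert match.author_class is AuthorClass.EXACT

    def test_abbreviation_variants_count_as_exact(self):
        assert self._classified("Hook.f.", ["Hook.fil."]).author_class is AuthorClass.EXACT


class TestSecondRound:
    def _backbone(self):
        store = TaxonStore(SourceDb.GBIF)
        accepted = _record("A", "Rosa inodora", "Fr.")
        synonym = _record("S", "Rosa elliptica", "Tausch")
        synonym.status = Status.SYNONYM
        synonym.accepted_id = "A"
        store.add(accepted)
        store.add(synonym)
        return store, accepted

    def test_no_synonyms_and_no_match_yields_none(self):
        store = TaxonStore(SourceDb.GBIF)
        lonely = _record("L", "Poa annua", "L.")
        store.add(lonely)
        [match] = second_round_via_synonyms([lonely], store, [])
        assert match.category is MatchCategory.NONE

    def test_match_via_planted_synonym(self):
        store, accepted = self._backbone()
        reference = _record("N", "Rosa elliptica", db=SourceDb.NCBI, authorships=["Tausch"])
        [match] = second_round_via_synonyms([accepted], store, [reference])
        assert match.category is MatchCategory.EXACT
        assert match.via_synonym == "S"
        assert match.query.taxon_id == "A"
        # the comparison is about the synonym's citation, not the accepted name's
        assert classify_match_authors(match).author_class is AuthorClass.EXACT

    def test_second_round_never_overrides_first_round(self):
        """Queries matched in round one are disjoint from round-two input."""
        world = generate_world(WorldConfig(n_species=60, seed=3, rate_synonym_pair=0.2))
        queries = [r for r in world.backbone if r.status is Status.ACCEPTED]
        references = [
            r for r in world.ncbi if r.rank is Rank.SPECIES and r.status is Status.ACCEPTED
        ]
        first = match_names(queries, references)
        matched_first = {
            m.query.taxon_id
            for m in first
            if m.category in (MatchCategory.EXACT, MatchCategory.FUZZY)
        }
        unmatched = [q for q in queries if q.taxon_id not in matched_first]
        second = second_round_via_synonyms(unmatched, world.backbone, references)
        assert {m.query.taxon_id for m in second}.isdisjoint(matched_first)

    def test_clean_world_all_exact_author_exact(self, clean_world):
        queries = [r for r in clean_world.backbone if r.status is Status.ACCEPTED]
        references = [
            r for r in clean_world.ncbi if r.rank is Rank.SPECIES and r.status is Status.ACCEPTED
        ]
        matches = [classify_match_authors(m) for m in match_names(queries, references)]
        assert all(m.category is MatchCategory.EXACT for m in matches)
        assert all(m.author_class is AuthorClass.EXACT for m in matches)
        assert len({m.query.taxon_id for m in matches}) == len(queries)
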