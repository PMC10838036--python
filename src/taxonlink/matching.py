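"""Name matching between a query set (GBIF accepted names) and a
reference set (NCBI names), with author-based refinement and a
synonym-mediated second round.

Match categories follow the conventions of taxonomic name-diff tools:
``exact`` (equal canonical names, case-insensitive), ``fuzzy`` (small
edit distance, covering misspellings, or equality after folding the
Latin gender endings -us/-a/-um of the terminal epithet), and
``partial_exact`` (only the genus agrees).  Partial matches are computed
and reported but flagged excluded — genus-only agreement says nothing
about the species — so the exclusion itself is visible and testable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .io_formats import TaxonStore, get_synonyms
from .name_parsing import (
    AuthorComparison,
    ComparisonOutcome,
    ParsedName,
    compare_authorship,
    parse_name,
)
from .records import TaxonRecord

__all__ = [
    "MatchCategory",
    "AuthorClass",
    "NameMatch",
    "match_names",
    "classify_match_authors",
    "second_round_via_synonyms",
    "rank_candidates",
    "write_matches",
]


class MatchCategory(str, enum.Enum):
    EXACT = "exact"
    FUZZY = "fuzzy"
    PARTIAL_EXACT = "partial_exact"
    NONE = "none"


class AuthorClass(str, enum.Enum):
    EXACT = "exact"
    NOAUTHOR = "noauthor"
    AUTHOR_MISMATCH = "author_mismatch"
    NOT_APPLICABLE = "not_applicable"


#: ranking priority: author-exact candidates first, mismatches last
_AUTHOR_PRIORITY = {
    AuthorClass.EXACT: 0,
    AuthorClass.NOAUTHOR: 1,
    AuthorClass.AUTHOR_MISMATCH: 2,
    AuthorClass.NOT_APPLICABLE: 3,
}

_GENDER_ENDINGS = ("us", "um", "a")


@dataclass
class NameMatch:
    query: TaxonRecord
    reference: TaxonRecord | None
    category: MatchCategory
    author_class: AuthorClass = AuthorClass.NOT_APPLICABLE
    edit_distance: int = 0
    via_synonym: str = ""
    via_synonym_record: TaxonRecord | None = None
    stem_fold: bool = False
    excluded: bool = False
    author_comparison: AuthorComparison | None = None


def _edit_distance(a: str, b: str, limit: int | None = None) -> int:
    if a == b:
        return 0
    k = -1 if limit is None else limit
    result = edlib.align(a, b, task="distance", k=k)
    distance = result["editDistance"]
    if distance == -1:
        return (limit or 0) + 1
    return distance


def _stem_fold(canonical: str) -> str:
    """Fold the Latin gender ending of the terminal epithet."""
    words = canonical.split()
    if not words:
        return canonical
    last = words[-1]
    for ending in _GENDER_ENDINGS:
        if last.endswith(ending) and len(last) > len(ending) + 2:
            words[-1] = last[: -len(ending)] + "~"
            break
    return " ".join(words)


def match_names(
    queries: Sequence[TaxonRecord],
    references: Sequence[TaxonRecord],
    fuzzy_threshold: int = 1,
) -> list[NameMatch]:
    """All candidate matches for each query; every query yields at least
    one record (``category=none`` when nothing matched).

    Exact candidates suppress the fuzzy scan for that query; genus-only
    (partial) candidates are only reported when neither exact nor fuzzy
    candidates exist, and arrive pre-flagged ``excluded``.
    """
    by_canonical: dict[str, list[TaxonRecord]] = {}
    by_genus: dict[str, list[TaxonRecord]] = {}
    named_refs = [r for r in references if r.canonical_name]
    for ref in named_refs:
        by_canonical.setdefault(ref.canonical_name.casefold(), []).append(ref)
        genus = ref.canonical_name.split()[0].casefold()
        by_genus.setdefault(genus, []).append(ref)

    matches: list[NameMatch] = []
    for query in queries:
        canonical = query.canonical_name.casefold()
        candidates: list[NameMatch] = []
        for ref in by_canonical.get(canonical, []):
            candidates.append(NameMatch(query, ref, MatchCategory.EXACT, edit_distance=0))
        if not candidates:
            folded = _stem_fold(canonical)
            for ref in named_refs:
                ref_canonical = ref.canonical_name.casefold()
                distance = _edit_distance(canonical, ref_canonical, fuzzy_threshold)
                if 0 < distance <= fuzzy_threshold:
                    candidates.append(
                        NameMatch(query, ref, MatchCategory.FUZZY, edit_distance=distance)
                    )
                elif folded != canonical and folded == _stem_fold(ref_canonical):
                    candidates.append(
                        NameMatch(
                            query,
                            ref,
                            MatchCategory.FUZZY,
                            edit_distance=_edit_distance(canonical, ref_canonical),
                            stem_fold=True,
                        )
                    )
        if not candidates:
            genus = canonical.split()[0] if canonical else ""
            for ref in by_genus.get(genus, []):
                candidates.append(
                    NameMatch(
                        query,
                        ref,
                        MatchCategory.PARTIAL_EXACT,
                        edit_distance=_edit_distance(canonical, ref.canonical_name.casefold()),
                        excluded=True,
                    )
                )
        if not candidates:
            candidates.append(NameMatch(query, None, MatchCategory.NONE))
        matches.extend(candidates)
    return matches


def _parsed_with_citation(record: TaxonRecord, citation: str) -> ParsedName:
    """A ParsedName for a record with an explicit author citation."""
    text = f"{record.canonical_name} {citation}".strip()
    return parse_name(text or record.scientific_name)


def classify_match_authors(match: NameMatch) -> NameMatch:
    """Set ``author_class`` from the author-citation comparison.

    NCBI records may carry several authority citations; each is tried and
    the best outcome kept (identical or normalised match beats absent
    beats mismatch), since the extra citations are genuinely stored in
    the dump.
    """
    if match.category not in (MatchCategory.EXACT, MatchCategory.FUZZY):
        match.author_class = AuthorClass.NOT_APPLICABLE
        return match
    assert match.reference is not None
    # a synonym-mediated match is an assertion about the synonym's name,
    # so its author citation is the one to compare
    query_record = match.via_synonym_record or match.query
    query_parsed = _parsed_with_citation(query_record, query_record.authorship)
    citations = match.reference.authorships or ("",)
    best: AuthorComparison | None = None
    for citation in citations:
        ref_parsed = _parsed_with_citation(match.reference, citation)
        comparison = compare_authorship(query_parsed, ref_parsed)
        if best is None or _outcome_priority(comparison.outcome) < _outcome_priority(best.outcome):
            best = comparison
    assert best is not None
    match.author_comparison = best
    if best.outcome in (ComparisonOutcome.IDENTICAL, ComparisonOutcome.NORMALIZED_MATCH):
        match.author_class = AuthorClass.EXACT
    elif best.outcome is ComparisonOutcome.ABSENT:
        match.author_class = AuthorClass.NOAUTHOR
    else:
        match.author_class = AuthorClass.AUTHOR_MISMATCH
    return match


def _outcome_priority(outcome: ComparisonOutcome) -> int:
    return {
        ComparisonOutcome.IDENTICAL: 0,
        ComparisonOutcome.NORMALIZED_MATCH: 1,
        ComparisonOutcome.ABSENT: 2,
        ComparisonOutcome.MISMATCH: 3,
    }[outcome]


def second_round_via_synonyms(
    unmatched_queries: Sequence[TaxonRecord],
    backbone: TaxonStore,
    references: Sequence[TaxonRecord],
    fuzzy_threshold: int = 1,
) -> list[NameMatch]:
    """Second matching round through GBIF synonyms.

    For queries with no first-round exact/fuzzy match, each GBIF synonym
    of the accepted name is matched against the references; successful
    matches carry ``via_synonym`` = the synonym's taxonID.  This covers
    taxa whose accepted name differs between the two databases.
    """
    matches: list[NameMatch] = []
    for query in unmatched_queries:
        synonyms = get_synonyms(backbone, query.taxon_id)
        found: list[NameMatch] = []
        for synonym in synonyms:
            for candidate in match_names([synonym], references, fuzzy_threshold):
                if candidate.category in (MatchCategory.EXACT, MatchCategory.FUZZY):
                    candidate.via_synonym = synonym.taxon_id
                    candidate.via_synonym_record = synonym
                    candidate.query = query
                    found.append(candidate)
        matches.extend(found if found else [NameMatch(query, None, MatchCategory.NONE)])
    return matches


def rank_candidates(candidates: Iterable[NameMatch]) -> list[NameMatch]:
    """Deterministic candidate order: author class, then edit distance,
    then reference identifier."""
    return sorted(
        candidates,
        key=lambda m: (
            _AUTHOR_PRIORITY[m.author_class],
            m.edit_distance,
            m.reference.taxon_id if m.reference else "",
        ),
    )


def write_matches(matches: Iterable[NameMatch], path: str | Path) -> None:
    header = ["query_id", "reference_id", "category", "author_class", "edit_distance", "via_synonym", "excluded"]
    lines = ["\t".join(header)]
    for match in matches:
        lines.append(
            "\t".join(
                [
                    match.query.taxon_id,
                    match.reference.taxon_id if match.reference else "",
                    match.category.value,
                    match.author_class.value,
                    str(match.edit_distance),
                    match.via_synonym,
                    "yes" if match.excluded else "no",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
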