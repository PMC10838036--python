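"""Curation triage: combine match category, author class, Wikidata
linking evidence and GBIF status into exactly one curation action per
checklist name.

The decision function is a first-match rule list over a finite input
space.  Each rule row is a tuple of conditions (``None`` = wildcard,
i.e. the condition is not evaluated) mirroring the columns of the
workflow's outcome table: name-match type, whether the GBIF id is linked
to a Wikidata item, whether that item links an NCBI id, whether the
name-matched NCBI id agrees with Wikidata's, whether a reverse (NCBI →
GBIF) link was found, and whether the name is currently accepted in the
GBIF Backbone.  Combinations not covered by any row fall through to
``OTHER`` (manual curation), so the function is total by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .matching import AuthorClass, MatchCategory, NameMatch, rank_candidates
from .name_parsing import ComparisonOutcome
from .records import ChecklistEntry, Status
from .wikidata import LinkEvidence

__all__ = [
    "Action",
    "CurationCase",
    "HomonymFlag",
    "triage_case",
    "assemble_case",
    "flag_homonyms",
    "summarize",
    "write_curation_table",
]


class Action(str, enum.Enum):
    A_NO_MATCH = "a"
    B_AUTO_ACCEPT = "b"
    C_VERIFY_UPDATE_NCBI = "c"
    D_BATCH_ADD_NCBI = "d"
    E_BATCH_UPDATE_GBIF = "e"
    F_VERIFY_SYNONYM = "f"
    G_VERIFY_AUTHORSHIP = "g"
    H_POSSIBLE_HOMONYM = "h"
    OTHER = "other"


class MatchType(str, enum.Enum):
    """Name-match type in the sense of the outcome table: an exact name
    match is subdivided by its author comparison."""

    NONE = "none"
    EXACT = "exact"
    NOAUTHOR = "noauthor"
    AUTHOR_MISMATCH = "author_mismatch"
    FUZZY = "fuzzy"


class Tristate(str, enum.Enum):
    YES = "yes"
    NO = "no"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class CurationCase:
    entry: ChecklistEntry
    best_match: NameMatch | None
    evidence: LinkEvidence
    gbif_status: Status
    action: Action = Action.OTHER
    ncbi_agrees_with_wikidata: Tristate = Tristate.NOT_APPLICABLE
    query_kingdom: str = ""
    reference_kingdom: str = ""
    candidates: list[NameMatch] = field(default_factory=list)


class HomonymKind(str, enum.Enum):
    WITHIN_CODE = "within_code"
    HEMIHOMONYM = "hemihomonym"


@dataclass
class HomonymFlag:
    case: CurationCase
    conflicting_authors: tuple[str, str]
    kind: HomonymKind


# rule rows: (match_type, gbif_linked, wd_links_ncbi, ncbi_same,
#             reverse_linked, status_accepted) -> action; None = wildcard.
_RULES: list[tuple[tuple, Action]] = [
    ((MatchType.NONE, False, None, None, False, None), Action.A_NO_MATCH),
    ((MatchType.NONE, False, None, None, True, None), Action.OTHER),
    ((MatchType.EXACT, True, True, True, None, None), Action.B_AUTO_ACCEPT),
    ((MatchType.EXACT, True, True, False, None, None), Action.C_VERIFY_UPDATE_NCBI),
    ((MatchType.EXACT, True, False, None, False, None), Action.D_BATCH_ADD_NCBI),
    ((MatchType.EXACT, True, False, None, True, None), Action.OTHER),
    ((MatchType.EXACT, False, None, None, True, True), Action.E_BATCH_UPDATE_GBIF),
    ((MatchType.EXACT, False, None, None, True, False), Action.F_VERIFY_SYNONYM),
    ((MatchType.NOAUTHOR, True, True, True, None, None), Action.G_VERIFY_AUTHORSHIP),
    ((MatchType.NOAUTHOR, True, None, False, None, None), Action.H_POSSIBLE_HOMONYM),
    ((MatchType.AUTHOR_MISMATCH, True, True, True, None, None), Action.G_VERIFY_AUTHORSHIP),
    ((MatchType.AUTHOR_MISMATCH, True, None, False, None, None), Action.H_POSSIBLE_HOMONYM),
    ((MatchType.FUZZY, None, None, None, None, None), Action.OTHER),
]

_AUTO_ACTIONS = frozenset(
    {Action.B_AUTO_ACCEPT, Action.D_BATCH_ADD_NCBI, Action.E_BATCH_UPDATE_GBIF}
)


def match_type_of(match: NameMatch | None) -> MatchType:
    if match is None or match.reference is None or match.excluded:
        return MatchType.NONE
    if match.category is MatchCategory.FUZZY:
        return MatchType.FUZZY
    if match.category is not MatchCategory.EXACT:
        return MatchType.NONE
    return {
        AuthorClass.EXACT: MatchType.EXACT,
        AuthorClass.NOAUTHOR: MatchType.NOAUTHOR,
        AuthorClass.AUTHOR_MISMATCH: MatchType.AUTHOR_MISMATCH,
        AuthorClass.NOT_APPLICABLE: MatchType.EXACT,
    }[match.author_class]


def triage_case(
    best_match: NameMatch | None, evidence: LinkEvidence, gbif_status: Status
) -> Action:
    """Assign the curation action for one checklist name.  Total: every
    input combination yields exactly one action.

    A match obtained only through a GBIF synonym never triggers an
    automatic action (accept or batch edit): designating a synonym is a
    revisable taxonomic assertion, so such cases are demoted to the
    synonym-verification queue (action f).
    """
    mtype = match_type_of(best_match)
    matched_ncbi = (
        best_match.reference.taxon_id
        if best_match is not None and best_match.reference is not None and not best_match.excluded
        else ""
    )
    conditions = (
        mtype,
        evidence.gbif_linked,
        bool(evidence.wd_ncbi_id),
        bool(matched_ncbi) and matched_ncbi == evidence.wd_ncbi_id,
        evidence.reverse_item is not None,
        gbif_status is Status.ACCEPTED,
    )
    action = Action.OTHER
    for row, row_action in _RULES:
        if all(want is None or want == have for want, have in zip(row, conditions)):
            action = row_action
            break
    if best_match is not None and best_match.via_synonym and action in _AUTO_ACTIONS:
        action = Action.F_VERIFY_SYNONYM
    return action


def assemble_case(
    entry: ChecklistEntry,
    candidates: Sequence[NameMatch],
    evidence: LinkEvidence,
    gbif_status: Status,
    reference_kingdom: str = "",
) -> CurationCase:
    """Rank the candidate matches, pick the best, and triage.

    When the top two candidates tie exactly (same author class and edit
    distance against different references) the case goes to manual
    curation (OTHER) instead of trusting an arbitrary winner.
    """
    ranked = rank_candidates(
        [c for c in candidates if c.reference is not None and not c.excluded]
    )
    best = ranked[0] if ranked else None
    case = CurationCase(
        entry=entry,
        best_match=best,
        evidence=evidence,
        gbif_status=gbif_status,
        query_kingdom=entry.higher_taxon("kingdom"),
        reference_kingdom=reference_kingdom,
        candidates=list(ranked),
    )
    tied = (
        len(ranked) >= 2
        and (ranked[0].author_class, ranked[0].edit_distance)
        == (ranked[1].author_class, ranked[1].edit_distance)
    )
    if tied:
        case.action = Action.OTHER
    else:
        case.action = triage_case(best, evidence, gbif_status)
    matched_ncbi = best.reference.taxon_id if best and best.reference else ""
    if matched_ncbi and evidence.wd_ncbi_id:
        case.ncbi_agrees_with_wikidata = (
            Tristate.YES if matched_ncbi == evidence.wd_ncbi_id else Tristate.NO
        )
    return case


def flag_homonyms(cases: Iterable[CurationCase]) -> list[HomonymFlag]:
    """Flag every case whose author comparison is a genuine mismatch
    (orthographic variants that normalise equal are never flagged).

    The flag kind is ``hemihomonym`` when the two sides sit in different
    kingdoms — an identical name validly published under two independent
    nomenclatural codes — and ``within_code`` otherwise.
    """
    flags = []
    for case in cases:
        match = case.best_match
        if match is None or match.author_comparison is None:
            continue
        if match.author_comparison.outcome is not ComparisonOutcome.MISMATCH:
            continue
        kind = HomonymKind.WITHIN_CODE
        if (
            case.query_kingdom
            and case.reference_kingdom
            and case.query_kingdom != case.reference_kingdom
        ):
            kind = HomonymKind.HEMIHOMONYM
        ref_author = match.reference.authorship if match.reference else ""
        flags.append(
            HomonymFlag(
                case=case,
                conflicting_authors=(match.query.authorship, ref_author),
                kind=kind,
            )
        )
    return flags


def summarize(cases: Iterable[CurationCase]) -> dict[Action, int]:
    """Count cases per action; the counts sum to the number of cases."""
    counts = {action: 0 for action in Action}
    for case in cases:
        counts[case.action] += 1
    return counts


def write_curation_table(cases: Iterable[CurationCase], path: str | Path) -> None:
    """The main human-facing output: one row per checklist name with all
    gathered evidence and the assigned action letter."""
    header = [
        "gbif_taxon_id",
        "supplied_name",
        "match_category",
        "author_class",
        "matched_ncbi_id",
        "via_synonym",
        "gbif_linked_qid",
        "wd_ncbi_id",
        "reverse_qid",
        "reverse_gbif_id",
        "gbif_status",
        "ncbi_agrees_with_wikidata",
        "action",
    ]
    lines = ["\t".join(header)]
    for case in cases:
        match = case.best_match
        evidence = case.evidence
        lines.append(
            "\t".join(
                [
                    case.entry.gbif_taxon_id,
                    case.entry.supplied_name,
                    match.category.value if match else "none",
                    match.author_class.value if match else "not_applicable",
                    match.reference.taxon_id if match and match.reference else "",
                    match.via_synonym if match else "",
                    evidence.forward_item.qid if evidence.forward_item else "",
                    evidence.wd_ncbi_id,
                    evidence.reverse_item.qid if evidence.reverse_item else "",
                    evidence.reverse_item.gbif_id if evidence.reverse_item else "",
                    case.gbif_status.value,
                    case.ncbi_agrees_with_wikidata.value,
                    case.action.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
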