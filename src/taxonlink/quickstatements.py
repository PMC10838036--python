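"""Batch-edit command generation in a QuickStatements-style text dialect.

Two curation actions produce batch edits: adding a missing NCBI taxonomy
ID (P685) to the item found by GBIF id, and updating a stale GBIF taxon
ID (P846) on the item found by reverse (NCBI) lookup.  A stale
identifier is never deleted: it is re-emitted with a deprecated rank and
a "reason for deprecated rank" qualifier (P2241) of "identifier
deprecated in the source database" (Q67125514), so future editors can
still trace the history.  Every statement carries a "retrieved" (P813)
reference date.

Serialised dialect (one command per line, tab-separated fields)::

    <subject-QID> TAB <property> TAB "<value>" [TAB RANK TAB deprecated]
        [TAB <qualifier-property> TAB <qualifier-value>]...
        [TAB S<ref-property-number> TAB <ref-value>]...

String values are double-quoted; item values (Q-ids) and dates are bare.
Dates use day precision: ``+YYYY-MM-DDT00:00:00Z/11``.  The ``RANK``
field pair is this package's documented extension for rank changes,
which the line-oriented v1 dialect lacks.  :func:`parse` reads the
dialect back, so batches round-trip.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from typing import Iterable

from .triage import Action, CurationCase

__all__ = ["QuickStatement", "statements_for_case", "render", "parse", "format_date"]

DEPRECATED_REASON_PROPERTY = "P2241"
DEPRECATED_IN_SOURCE = "Q67125514"
RETRIEVED_PROPERTY = "P813"

_QID_RE = re.compile(r"^Q[0-9]+$")
_DATE_RE = re.compile(r"^\+\d{4}-\d{2}-\d{2}T00:00:00Z/11$")


@dataclass
class QuickStatement:
    subject_qid: str
    property: str  # P846 or P685
    value: str  # bare identifier, never a URL
    rank: str = "normal"  # "normal" | "deprecated"
    qualifiers: list[tuple[str, str]] = field(default_factory=list)
    references: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.property not in ("P846", "P685"):
            raise ValueError(f"unsupported property {self.property!r}")
        if self.value.startswith(("http://", "https://")):
            raise ValueError("statement values must be bare identifiers, not URLs")
        if self.rank == "deprecated" and (
            (DEPRECATED_REASON_PROPERTY, DEPRECATED_IN_SOURCE) not in self.qualifiers
        ):
            raise ValueError("deprecated-rank statements require the P2241 reason qualifier")


def format_date(date: datetime.date) -> str:
    """Wikidata time literal at day precision (/11)."""
    return f"+{date.isoformat()}T00:00:00Z/11"


def statements_for_case(case: CurationCase, retrieved: datetime.date) -> list[QuickStatement]:
    """Batch-edit statements for an action-d or action-e case.

    Action d (NCBI id missing from Wikidata): one add-statement for P685
    on the forward-linked item.  Action e (stale GBIF id on Wikidata):
    an add-statement for the currently accepted GBIF id plus a
    deprecated-rank statement preserving the stale id, both on the
    reverse-linked item.
    """
    reference = [(RETRIEVED_PROPERTY, format_date(retrieved))]
    if case.action is Action.D_BATCH_ADD_NCBI:
        if case.evidence.forward_item is None or case.best_match is None:
            raise ValueError("action-d case lacks a forward-linked item or a match")
        assert case.best_match.reference is not None
        return [
            QuickStatement(
                subject_qid=case.evidence.forward_item.qid,
                property="P685",
                value=case.best_match.reference.taxon_id,
                references=list(reference),
            )
        ]
    if case.action is Action.E_BATCH_UPDATE_GBIF:
        item = case.evidence.reverse_item
        if item is None:
            raise ValueError("action-e case lacks a reverse-linked item")
        statements = [
            QuickStatement(
                subject_qid=item.qid,
                property="P846",
                value=case.entry.gbif_taxon_id,
                references=list(reference),
            )
        ]
        if item.gbif_id and item.gbif_id != case.entry.gbif_taxon_id:
            statements.append(
                QuickStatement(
                    subject_qid=item.qid,
                    property="P846",
                    value=item.gbif_id,
                    rank="deprecated",
                    qualifiers=[(DEPRECATED_REASON_PROPERTY, DEPRECATED_IN_SOURCE)],
                    references=list(reference),
                )
            )
        return statements
    raise ValueError(f"no batch edits defined for action {case.action.value!r}")


def _render_value(value: str) -> str:
    if _QID_RE.match(value) or _DATE_RE.match(value):
        return value
    return f'"{value}"'


def render(statements: Iterable[QuickStatement]) -> str:
    """Serialise statements to the documented dialect; byte-stable and
    injective on distinct statement sequences."""
    lines = []
    for st in statements:
        fields = [st.subject_qid, st.property, _render_value(st.value)]
        if st.rank == "deprecated":
            fields += ["RANK", "deprecated"]
        for prop, value in st.qualifiers:
            if st.rank == "deprecated" and (prop, value) == (
                DEPRECATED_REASON_PROPERTY,
                DEPRECATED_IN_SOURCE,
            ):
                continue  # implied by the RANK field; re-added on parse
            fields += [prop, _render_value(value)]
        for prop, value in st.references:
            fields += ["S" + prop.lstrip("P"), _render_value(value)]
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def parse(text: str) -> list[QuickStatement]:
    """Read the dialect back; inverse of :func:`render`."""
    statements = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected at least 3 fields")
        subject, prop, value = fields[0], fields[1], _unquote(fields[2])
        rank = "normal"
        qualifiers: list[tuple[str, str]] = []
        references: list[tuple[str, str]] = []
        rest = fields[3:]
        if len(rest) % 2:
            raise ValueError(f"line {lineno}: dangling field {rest[-1]!r}")
        for key, raw in zip(rest[::2], rest[1::2]):
            if key == "RANK":
                rank = raw
            elif key.startswith("S"):
                references.append(("P" + key[1:], _unquote(raw)))
            else:
                qualifiers.append((key, _unquote(raw)))
        if rank == "deprecated" and (
            (DEPRECATED_REASON_PROPERTY, DEPRECATED_IN_SOURCE) not in qualifiers
        ):
            qualifiers.insert(0, (DEPRECATED_REASON_PROPERTY, DEPRECATED_IN_SOURCE))
        statements.append(
            QuickStatement(
                subject_qid=subject,
                property=prop,
                value=value,
                rank=rank,
                qualifiers=qualifiers,
                references=references,
            )
        )
    return statements


def _unquote(raw: str) -> str:
    if len(raw) >= 2 and raw.startswith('"') and raw.endswith('"'):
        return raw[1:-1]
    return raw
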