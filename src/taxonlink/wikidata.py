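"""Wikidata taxon items as identifier-linking evidence.

Wikidata models external database identifiers as statements on a taxon
item: "GBIF taxon ID" (P846) and "NCBI taxonomy ID" (P685), with the
taxon name under P225 and the author under P405.  This module works from
an offline tabular snapshot of those claims (one row per claim value),
provides the forward (by GBIF id) and reverse (by NCBI id) lookups the
linking workflow needs, and generates the batched SPARQL that would
retrieve the same snapshot from the live query endpoint.  No code path
here performs network access.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "WikidataTaxonItem",
    "LinkEvidence",
    "WikidataSnapshot",
    "lookup_by_gbif",
    "lookup_by_ncbi",
    "gather_evidence",
    "build_sparql",
]

_QID_RE = re.compile(r"^Q[0-9]+$")

#: claims per VALUES block in generated SPARQL; endpoint practicality
DEFAULT_BATCH_SIZE = 1000


@dataclass
class WikidataTaxonItem:
    """One item's linking claims.  ``gbif_id_rank`` is "deprecated" when
    the P846 statement carries a deprecated rank on Wikidata."""

    qid: str
    taxon_name: str = ""
    taxon_author: str = ""
    gbif_id: str = ""
    ncbi_id: str = ""
    gbif_id_rank: str = "normal"
    retrieved: str = ""

    def __post_init__(self) -> None:
        if not _QID_RE.match(self.qid):
            raise ValueError(f"not a QID: {self.qid!r}")


@dataclass
class LinkEvidence:
    """Evidence gathered for one checklist name.

    ``forward_item`` is the item found by the checklist's GBIF id (when
    any); ``reverse_item`` is the item found by the name-matched NCBI id,
    populated only when the forward lookup failed.
    """

    gbif_linked: bool = False
    wd_ncbi_id: str = ""
    forward_item: WikidataTaxonItem | None = None
    reverse_item: WikidataTaxonItem | None = None


class WikidataSnapshot:
    """An offline set of taxon items with indexes on both identifiers.

    Items with multiple values for one property appear as one row per
    value in the TSV serialisation, hence possibly several items per
    QID here; lookups return every matching row.
    """

    COLUMNS = ("qid", "p225", "p405", "p846", "p685", "p846_rank", "retrieved")

    def __init__(self, items: Iterable[WikidataTaxonItem] = ()):
        self.items: list[WikidataTaxonItem] = list(items)
        self._by_gbif: dict[str, list[WikidataTaxonItem]] = {}
        self._by_ncbi: dict[str, list[WikidataTaxonItem]] = {}
        for item in self.items:
            if item.gbif_id:
                self._by_gbif.setdefault(item.gbif_id, []).append(item)
            if item.ncbi_id:
                self._by_ncbi.setdefault(item.ncbi_id, []).append(item)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def by_gbif(self, gbif_id: str) -> list[WikidataTaxonItem]:
        return list(self._by_gbif.get(gbif_id, []))

    def by_ncbi(self, ncbi_id: str) -> list[WikidataTaxonItem]:
        return list(self._by_ncbi.get(ncbi_id, []))

    @classmethod
    def read(cls, path: str | Path) -> "WikidataSnapshot":
        path = Path(path)
        with open(path, encoding="utf-8", errors="replace") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != list(cls.COLUMNS):
                raise ValueError(f"{path}: expected columns {cls.COLUMNS}, got {header}")
            items = []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                fields += [""] * (len(cls.COLUMNS) - len(fields))
                qid, p225, p405, p846, p685, p846_rank, retrieved = fields[:7]
                items.append(
                    WikidataTaxonItem(
                        qid=qid,
                        taxon_name=p225,
                        taxon_author=p405,
                        gbif_id=p846,
                        ncbi_id=p685,
                        gbif_id_rank=p846_rank or "normal",
                        retrieved=retrieved,
                    )
                )
        return cls(items)

    def write(self, path: str | Path) -> None:
        lines = ["\t".join(self.COLUMNS)]
        for item in self.items:
            lines.append(
                "\t".join(
                    [
                        item.qid,
                        item.taxon_name,
                        item.taxon_author,
                        item.gbif_id,
                        item.ncbi_id,
                        item.gbif_id_rank,
                        item.retrieved,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def lookup_by_gbif(snapshot: WikidataSnapshot, gbif_id: str) -> list[WikidataTaxonItem]:
    """All items whose GBIF taxon ID claim (P846) equals ``gbif_id``."""
    return snapshot.by_gbif(gbif_id)


def lookup_by_ncbi(snapshot: WikidataSnapshot, ncbi_id: str) -> list[WikidataTaxonItem]:
    """All items whose NCBI taxonomy ID claim (P685) equals ``ncbi_id``."""
    return snapshot.by_ncbi(ncbi_id)


def gather_evidence(
    snapshot: WikidataSnapshot, gbif_id: str, matched_ncbi_id: str = ""
) -> LinkEvidence:
    """Forward lookup by GBIF id; reverse lookup by the name-matched NCBI
    id only when the forward lookup found nothing.

    With several forward hits (a planted or genuine double link) the
    first snapshot row wins here; triage sees the multiplicity through
    the snapshot lookups directly.
    """
    forward = lookup_by_gbif(snapshot, gbif_id)
    if forward:
        item = forward[0]
        return LinkEvidence(gbif_linked=True, wd_ncbi_id=item.ncbi_id, forward_item=item)
    if matched_ncbi_id:
        reverse = lookup_by_ncbi(snapshot, matched_ncbi_id)
        if reverse:
            return LinkEvidence(gbif_linked=False, reverse_item=reverse[0])
    return LinkEvidence()


_SPARQL_TEMPLATE = """\
PREFIX wd: <http://www.wikidata.org/entity/>
PREFIX wdt: <http://www.wikidata.org/prop/direct/>
SELECT ?item ?taxonName ?taxonAuthor ?gbifId ?ncbiId WHERE {{
  VALUES ?lookup {{ {values} }}
  ?item wdt:{prop} ?lookup .
  OPTIONAL {{ ?item wdt:P225 ?taxonName . }}
  OPTIONAL {{ ?item wdt:P405 ?taxonAuthorItem . }}
  OPTIONAL {{ ?item wdt:P846 ?gbifId . }}
  OPTIONAL {{ ?item wdt:P685 ?ncbiId . }}
  BIND(STR(?taxonAuthorItem) AS ?taxonAuthor)
}}
"""


def build_sparql(
    ids: Sequence[str], prop: str, batch_size: int = DEFAULT_BATCH_SIZE
) -> list[str]:
    """SPARQL queries selecting the linking claims for items whose
    ``prop`` (P846 or P685) value is among ``ids``.

    Ids are batched ``batch_size`` per VALUES block; output is
    byte-stable for fixed input.
    """
    if prop not in ("P846", "P685"):
        raise ValueError(f"property must be P846 or P685, got {prop!r}")
    if not ids:
        raise ValueError("empty identifier list")
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    queries = []
    for start in range(0, len(ids), batch_size):
        batch = ids[start : start + batch_size]
        values = " ".join('"{}"'.format(i.replace('"', "")) for i in batch)
        queries.append(_SPARQL_TEMPLATE.format(values=values, prop=prop))
    return queries
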