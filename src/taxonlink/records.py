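"""Core record types shared across the toolkit.

A :class:`TaxonRecord` is one row of a taxonomic database — either the GBIF
Backbone Taxonomy (where every name, accepted or synonym, has its own
taxonID) or the NCBI Taxonomy (where synonyms are merged under the accepted
taxonID and the old identifiers are deprecated).  A :class:`ChecklistEntry`
is one row of a GBIF "species list" download.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SourceDb(str, enum.Enum):
    GBIF = "GBIF"
    NCBI = "NCBI"


class Rank(str, enum.Enum):
    SPECIES = "species"
    GENUS = "genus"
    SUBSPECIES = "subspecies"
    OTHER = "other"


class Status(str, enum.Enum):
    ACCEPTED = "accepted"
    SYNONYM = "synonym"
    DOUBTFUL = "doubtful"
    DEPRECATED = "deprecated"
    MERGED = "merged"


#: ranks as they appear in GBIF exports, lower-cased, mapped onto our enum
_RANK_MAP = {
    "species": Rank.SPECIES,
    "genus": Rank.GENUS,
    "subspecies": Rank.SUBSPECIES,
}


def parse_rank(text: str) -> Rank:
    """Map a rank string (any case) onto the rank enum; unknown → other."""
    return _RANK_MAP.get(text.strip().lower(), Rank.OTHER)


@dataclass
class TaxonRecord:
    """One database entry: identifier, name, rank, status, accepted pointer.

    ``accepted_id`` is empty for self-accepted records.  ``parent_id`` is
    only populated for NCBI records (used for subtree walks).  NCBI may
    store several "authority" strings for one taxid; all are kept in
    ``authorships`` and ``authorship`` is the first of them.
    """

    source_db: SourceDb
    taxon_id: str
    scientific_name: str
    canonical_name: str = ""
    authorship: str = ""
    rank: Rank = Rank.OTHER
    status: Status = Status.ACCEPTED
    accepted_id: str = ""
    parent_id: str = ""
    authorships: tuple[str, ...] = ()
    dangling_accepted: bool = False  # accepted_id did not resolve at load time

    def __post_init__(self) -> None:
        if self.authorship and not self.authorships:
            self.authorships = (self.authorship,)

    @property
    def is_accepted(self) -> bool:
        return self.status is Status.ACCEPTED


@dataclass
class ChecklistEntry:
    """One row of a GBIF species-list download.

    ``higher_taxa`` holds the (rank, name, identifier) triples of the
    higher classification columns (kingdom, phylum, ...), in file order.
    Identifiers may be empty when the export omits the key columns.
    """

    supplied_name: str
    gbif_taxon_id: str
    status_at_import: Status = Status.ACCEPTED
    rank: Rank = Rank.OTHER
    higher_taxa: list[tuple[str, str, str]] = field(default_factory=list)

    def higher_taxon(self, rank_name: str) -> str:
        """Name of the higher taxon at ``rank_name`` ('' when absent)."""
        for rank, name, _ in self.higher_taxa:
            if rank == rank_name:
                return name
        return ""
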