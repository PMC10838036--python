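"""Readers, writers and in-store resolution for the tabular formats the
workflow touches: GBIF species-list exports, GBIF Backbone Taxonomy
flatfiles, and NCBI taxdump directories.

All formats are plain UTF-8 text.  The GBIF files are header-described
TSV without quoting (backslashes are treated literally); the taxdump uses
the NCBI convention of tab–pipe–tab field separators with a trailing
``\\t|``.  The writers emit exactly the dialects the readers consume, so
synthetic fixtures are indistinguishable from real dumps downstream.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .name_parsing import parse_name
from .records import ChecklistEntry, Rank, SourceDb, Status, TaxonRecord, parse_rank

logger = logging.getLogger("taxonlink.io")

__all__ = [
    "FormatError",
    "ResolutionError",
    "TaxonStore",
    "read_species_list",
    "write_species_list",
    "read_gbif_backbone",
    "write_gbif_backbone",
    "read_ncbi_taxdump",
    "write_ncbi_taxdump",
    "resolve_accepted",
    "subtree_species_names",
    "get_synonyms",
    "normalize_status",
]

#: accepted_id chains longer than this are reported as cycles; real GBIF
#: chains are at most two hops, deeper ones indicate corrupt data.
MAX_CHAIN_HOPS = 10

_HIGHER_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ResolutionError(ValueError):
    """An accepted_id chain could not be resolved (cycle or over-long)."""


def _load_status_vocabulary() -> dict[str, Status]:
    with resources.files("taxonlink.data").joinpath("status_vocabulary.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        data = yaml.safe_load(fh)
    return {k.lower(): Status(v) for k, v in data["statuses"].items()}


_STATUS_VOCAB = _load_status_vocabulary()


def normalize_status(text: str) -> Status:
    """Map a status string (any case) onto the status enum.

    Unknown strings map to ``doubtful`` with a warning, so that oddly
    labelled records are kept but never silently treated as accepted.
    """
    status = _STATUS_VOCAB.get(text.strip().lower())
    if status is None:
        logger.warning("unknown taxonomic status %r mapped to doubtful", text)
        return Status.DOUBTFUL
    return status


class TaxonStore:
    """Mapping taxon_id → TaxonRecord for one source database."""

    def __init__(self, source_db: SourceDb, records: Iterable[TaxonRecord] = ()):
        self.source_db = source_db
        self.records: dict[str, TaxonRecord] = {}
        for record in records:
            self.add(record)

    def add(self, record: TaxonRecord) -> None:
        if record.taxon_id in self.records:
            raise FormatError(f"duplicate taxon_id {record.taxon_id!r}")
        self.records[record.taxon_id] = record

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        return self.records[taxon_id]

    def get(self, taxon_id: str) -> TaxonRecord | None:
        return self.records.get(taxon_id)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TaxonStore)
            and self.source_db == other.source_db
            and self.records == other.records
        )

    def children_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for record in self:
            if record.parent_id and record.parent_id != record.taxon_id:
                index.setdefault(record.parent_id, []).append(record.taxon_id)
        return index


def _read_tsv(path: Path, required: tuple[str, ...]):
    """Yield (line_number, row_dict) for a header-described TSV file."""
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header line")
        header = header_line.split("\t")
        for column in required:
            if column not in header:
                raise FormatError(f"{path}: missing mandatory column {column!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(required):
                logger.error("%s:%d: unreadable row (%d fields), skipped", path, lineno, len(fields))
                continue
            fields += [""] * (len(header) - len(fields))
            yield lineno, dict(zip(header, fields))


def read_species_list(path: str | Path) -> list[ChecklistEntry]:
    """Read a GBIF "species list" export into checklist entries.

    Columns are located by header name, not position.  Higher-taxon
    columns (kingdom … genus, with optional ``<rank>Key`` identifier
    columns) are collected into ``higher_taxa``; empty cells become
    empty strings.
    """
    path = Path(path)
    entries = []
    for _, row in _read_tsv(path, ("taxonID", "scientificName", "taxonRank", "taxonomicStatus")):
        higher = []
        for rank_name in _HIGHER_RANKS:
            name = row.get(rank_name, "")
            key = row.get(rank_name + "Key", "")
            if name or key:
                higher.append((rank_name, name, key))
        entries.append(
            ChecklistEntry(
                supplied_name=row["scientificName"],
                gbif_taxon_id=row["taxonID"],
                status_at_import=normalize_status(row["taxonomicStatus"]),
                rank=parse_rank(row["taxonRank"]),
                higher_taxa=higher,
            )
        )
    return entries


def write_species_list(entries: Iterable[ChecklistEntry], path: str | Path) -> None:
    entries = list(entries)
    used_ranks = [
        r for r in _HIGHER_RANKS if any(any(h[0] == r for h in e.higher_taxa) for e in entries)
    ]
    header = ["taxonID", "scientificName", "taxonRank", "taxonomicStatus"]
    for rank_name in used_ranks:
        header += [rank_name, rank_name + "Key"]
    lines = ["\t".join(header)]
    for entry in entries:
        by_rank = {h[0]: h for h in entry.higher_taxa}
        row = [
            entry.gbif_taxon_id,
            entry.supplied_name,
            entry.rank.value,
            entry.status_at_import.value,
        ]
        for rank_name in used_ranks:
            _, name, key = by_rank.get(rank_name, (rank_name, "", ""))
            row += [name, key]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gbif_backbone(path: str | Path) -> TaxonStore:
    """Read a GBIF Backbone Taxonomy flatfile into a taxon store.

    Status strings are normalised case-insensitively (all synonym
    flavours collapse to ``synonym``).  A record whose acceptedNameUsageID
    does not occur in the file is kept, flagged ``dangling_accepted``.
    """
    path = Path(path)
    store = TaxonStore(SourceDb.GBIF)
    for _, row in _read_tsv(
        path, ("taxonID", "scientificName", "taxonRank", "taxonomicStatus")
    ):
        parsed = parse_name(row["scientificName"])
        canonical = row.get("canonicalName", "") or parsed.canonical
        authorship = row.get("scientificNameAuthorship", "") or parsed.authorship_verbatim
        accepted_id = row.get("acceptedNameUsageID", "")
        store.add(
            TaxonRecord(
                source_db=SourceDb.GBIF,
                taxon_id=row["taxonID"],
                scientific_name=row["scientificName"],
                canonical_name=canonical,
                authorship=authorship,
                rank=parse_rank(row["taxonRank"]),
                status=normalize_status(row["taxonomicStatus"]),
                accepted_id="" if accepted_id == row["taxonID"] else accepted_id,
            )
        )
    for record in store:
        if record.accepted_id and record.accepted_id not in store:
            record.dangling_accepted = True
            logger.warning(
                "backbone record %s: acceptedNameUsageID %s not in file",
                record.taxon_id,
                record.accepted_id,
            )
    return store


def write_gbif_backbone(store: TaxonStore, path: str | Path) -> None:
    header = [
        "taxonID",
        "scientificName",
        "scientificNameAuthorship",
        "canonicalName",
        "taxonRank",
        "taxonomicStatus",
        "acceptedNameUsageID",
    ]
    lines = ["\t".join(header)]
    for record in store:
        lines.append(
            "\t".join(
                [
                    record.taxon_id,
                    record.scientific_name,
                    record.authorship,
                    record.canonical_name,
                    record.rank.value,
                    record.status.value,
                    record.accepted_id,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_dmp(path: Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) rows of an NCBI .dmp file."""
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if not line.endswith("\t|"):
                raise FormatError(f"{path}:{lineno}: malformed dmp line (no trailing tab-pipe)")
            yield lineno, line[: -len("\t|")].split("\t|\t")


def read_ncbi_taxdump(directory: str | Path) -> TaxonStore:
    """Read an NCBI taxdump directory into a taxon store.

    ``names.dmp`` rows of class "scientific name" provide the name;
    "authority" rows (which repeat the binomen followed by the author
    citation) are parsed and their author citations attached to the same
    taxon_id — all of them, when several exist.  ``merged.dmp`` ids
    become ``merged`` records pointing at their target; ``delnodes.dmp``
    ids become ``deprecated`` records.
    """
    directory = Path(directory)
    names_path = directory / "names.dmp"
    nodes_path = directory / "nodes.dmp"
    if not names_path.exists() or not nodes_path.exists():
        raise FormatError(f"{directory}: names.dmp and nodes.dmp are required")

    nodes: dict[str, tuple[str, str]] = {}
    for lineno, fields in _read_dmp(nodes_path):
        if len(fields) < 3:
            raise FormatError(f"{nodes_path}:{lineno}: expected at least 3 fields")
        nodes[fields[0]] = (fields[1], fields[2])

    scientific: dict[str, str] = {}
    authorities: dict[str, list[str]] = {}
    for lineno, fields in _read_dmp(names_path):
        if len(fields) < 4:
            raise FormatError(f"{names_path}:{lineno}: expected 4 fields")
        taxon_id, name_txt, _unique, name_class = fields[:4]
        if name_class == "scientific name":
            scientific[taxon_id] = name_txt
        elif name_class == "authority":
            authorities.setdefault(taxon_id, []).append(name_txt)

    store = TaxonStore(SourceDb.NCBI)
    for taxon_id, (parent_id, rank_text) in nodes.items():
        name = scientific.get(taxon_id, "")
        parsed = parse_name(name) if name else None
        author_citations = tuple(
            parse_name(a).authorship_verbatim or a for a in authorities.get(taxon_id, [])
        )
        store.add(
            TaxonRecord(
                source_db=SourceDb.NCBI,
                taxon_id=taxon_id,
                scientific_name=name,
                canonical_name=parsed.canonical if parsed else "",
                authorship=author_citations[0] if author_citations else "",
                rank=parse_rank(rank_text),
                status=Status.ACCEPTED,
                parent_id="" if parent_id == taxon_id else parent_id,
                authorships=author_citations,
            )
        )

    merged_path = directory / "merged.dmp"
    if merged_path.exists():
        for lineno, fields in _read_dmp(merged_path):
            if len(fields) < 2:
                raise FormatError(f"{merged_path}:{lineno}: expected 2 fields")
            old_id, new_id = fields[0], fields[1]
            store.add(
                TaxonRecord(
                    source_db=SourceDb.NCBI,
                    taxon_id=old_id,
                    scientific_name="",
                    status=Status.MERGED,
                    accepted_id=new_id,
                )
            )

    delnodes_path = directory / "delnodes.dmp"
    if delnodes_path.exists():
        for lineno, fields in _read_dmp(delnodes_path):
            store.add(
                TaxonRecord(
                    source_db=SourceDb.NCBI,
                    taxon_id=fields[0],
                    scientific_name="",
                    status=Status.DEPRECATED,
                )
            )
    return store


def write_ncbi_taxdump(store: TaxonStore, directory: str | Path) -> None:
    """Write a store in the taxdump dialect (names/nodes/merged/delnodes)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names_lines, nodes_lines, merged_lines, delnodes_lines = [], [], [], []
    for record in store:
        if record.status is Status.MERGED:
            merged_lines.append(f"{record.taxon_id}\t|\t{record.accepted_id}\t|")
            continue
        if record.status is Status.DEPRECATED:
            delnodes_lines.append(f"{record.taxon_id}\t|")
            continue
        parent = record.parent_id or record.taxon_id
        nodes_lines.append(f"{record.taxon_id}\t|\t{parent}\t|\t{record.rank.value}\t|")
        if record.scientific_name:
            names_lines.append(
                f"{record.taxon_id}\t|\t{record.scientific_name}\t|\t\t|\tscientific name\t|"
            )
        for citation in record.authorships:
            full = f"{record.canonical_name} {citation}".strip()
            names_lines.append(f"{record.taxon_id}\t|\t{full}\t|\t\t|\tauthority\t|")
    (directory / "names.dmp").write_text("\n".join(names_lines) + "\n", encoding="utf-8")
    (directory / "nodes.dmp").write_text("\n".join(nodes_lines) + "\n", encoding="utf-8")
    (directory / "merged.dmp").write_text(
        "\n".join(merged_lines) + ("\n" if merged_lines else ""), encoding="utf-8"
    )
    (directory / "delnodes.dmp").write_text(
        "\n".join(delnodes_lines) + ("\n" if delnodes_lines else ""), encoding="utf-8"
    )


def resolve_accepted(store: TaxonStore, taxon_id: str) -> TaxonRecord | None:
    """Follow accepted_id / merged pointers to the currently accepted record.

    Returns ``None`` for doubtful, deleted and unknown identifiers.  A
    chain longer than :data:`MAX_CHAIN_HOPS`, or one that revisits an
    identifier, raises :class:`ResolutionError`.
    """
    seen: list[str] = []
    current_id = taxon_id
    for _ in range(MAX_CHAIN_HOPS + 1):
        if current_id in seen:
            raise ResolutionError(f"accepted_id cycle: {' -> '.join(seen + [current_id])}")
        seen.append(current_id)
        record = store.get(current_id)
        if record is None:
            return None
        if record.status in (Status.DOUBTFUL, Status.DEPRECATED):
            return None
        if not record.accepted_id or record.accepted_id == record.taxon_id:
            return record
        current_id = record.accepted_id
    raise ResolutionError(
        f"accepted_id chain from {taxon_id} exceeds {MAX_CHAIN_HOPS} hops: "
        + " -> ".join(seen)
    )


def subtree_species_names(
    store: TaxonStore, root_id: str, rank: Rank | None = Rank.SPECIES
) -> list[TaxonRecord]:
    """Records under ``root_id`` (inclusive) at the given rank.

    Restricting the reference names to one subtree (e.g. the green
    plants) both shrinks the search space and avoids hemihomonyms:
    an identically named animal genus lives outside the subtree and is
    simply never offered as a match candidate.
    """
    if root_id not in store:
        raise KeyError(f"unknown root taxon_id {root_id!r}")
    children = store.children_index()
    result = []
    stack = [root_id]
    while stack:
        node = stack.pop()
        record = store[node]
        if rank is None or record.rank == rank:
            result.append(record)
        stack.extend(reversed(children.get(node, [])))
    return result


def get_synonyms(store: TaxonStore, accepted_id: str) -> list[TaxonRecord]:
    """All records whose accepted_id chain terminates at ``accepted_id``,
    excluding the accepted record itself."""
    target_id = accepted_id
    hops = 0
    current = store.get(accepted_id)
    while current is not None and current.accepted_id and hops <= MAX_CHAIN_HOPS:
        target_id = current.accepted_id
        current = store.get(current.accepted_id)
        hops += 1
    synonyms = []
    for record in store:
        if record.taxon_id == target_id:
            continue
        endpoint = record.taxon_id
        hops = 0
        current: TaxonRecord | None = record
        while current is not None and current.accepted_id and hops <= MAX_CHAIN_HOPS:
            endpoint = current.accepted_id
            current = store.get(current.accepted_id)
            hops += 1
        if endpoint == target_id:
            synonyms.append(record)
    return synonyms
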