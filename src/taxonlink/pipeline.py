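"""End-to-end identifier-linking run: filter → match → author-classify →
synonym round → Wikidata evidence → triage → summary → batch-edit export.

The pipeline operates on loaded stores (:func:`run_linking`) or on files
(:func:`run_pipeline`), writing a curation table, the match report, two
QuickStatements batches (one per automatic action) and a run summary.
All outputs are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_formats import (
    TaxonStore,
    read_gbif_backbone,
    read_ncbi_taxdump,
    read_species_list,
    resolve_accepted,
    subtree_species_names,
)
from .matching import (
    MatchCategory,
    NameMatch,
    classify_match_authors,
    match_names,
    second_round_via_synonyms,
    write_matches,
)
from .records import ChecklistEntry, Rank, TaxonRecord
from .triage import (
    Action,
    CurationCase,
    HomonymFlag,
    assemble_case,
    flag_homonyms,
    summarize,
    write_curation_table,
)
from .quickstatements import QuickStatement, render, statements_for_case
from .wikidata import WikidataSnapshot, gather_evidence

logger = logging.getLogger("taxonlink.pipeline")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "collect_candidates",
    "run_linking",
    "run_pipeline",
    "write_outputs",
]


@dataclass
class RunConfig:
    species_list: Path
    backbone: Path
    taxdump: Path
    wikidata_snapshot: Path
    output_dir: Path
    root_taxon_id: str = "33090"  # Viridiplantae in NCBI numbering
    fuzzy_threshold: int = 1
    retrieved: datetime.date = datetime.date(2023, 1, 1)
    reference_kingdom: str = ""  # checklist-vocabulary kingdom of the reference subtree
    seed: int = 0


@dataclass
class PipelineResult:
    cases: list[CurationCase]
    flags: list[HomonymFlag]
    summary: dict[Action, int]
    statements_add_ncbi: list[QuickStatement]
    statements_update_gbif: list[QuickStatement]
    dropped: list[tuple[ChecklistEntry, str]]
    matches: list[NameMatch] = field(default_factory=list)


def _prepare_queries(
    entries: Sequence[ChecklistEntry], backbone: TaxonStore
) -> tuple[list[tuple[ChecklistEntry, TaxonRecord]], list[tuple[ChecklistEntry, str]]]:
    """Species-rank filter plus resolution to currently accepted records.

    Returns (kept, dropped-with-reason).  Each kept entry is paired with
    its accepted backbone record and re-keyed to the accepted taxonID,
    since the backbone may have been revised after the checklist was
    exported.
    """
    kept: list[tuple[ChecklistEntry, TaxonRecord]] = []
    dropped: list[tuple[ChecklistEntry, str]] = []
    for entry in entries:
        if entry.rank is not Rank.SPECIES:
            dropped.append((entry, f"rank {entry.rank.value}, not species"))
            continue
        record = resolve_accepted(backbone, entry.gbif_taxon_id)
        if record is None:
            reason = (
                "doubtful or deleted in backbone"
                if entry.gbif_taxon_id in backbone
                else "taxonID not in backbone"
            )
            dropped.append((entry, reason))
            continue
        if record.taxon_id != entry.gbif_taxon_id:
            entry = dataclasses.replace(entry, gbif_taxon_id=record.taxon_id)
        kept.append((entry, record))
    for entry, reason in dropped:
        logger.info("dropped %s (%s): %s", entry.gbif_taxon_id, entry.supplied_name, reason)
    return kept, dropped


def collect_candidates(
    entries: Sequence[ChecklistEntry],
    backbone: TaxonStore,
    ncbi: TaxonStore,
    root_taxon_id: str = "33090",
    fuzzy_threshold: int = 1,
):
    """Filter/resolve the checklist, run both matching rounds and the
    author classification.

    Returns ``(kept, dropped, by_query)`` where ``by_query`` maps each
    accepted GBIF taxonID to its classified candidate matches.
    """
    kept, dropped = _prepare_queries(entries, backbone)
    # several checklist rows may resolve to one accepted record; match once
    queries = list({record.taxon_id: record for _, record in kept}.values())
    references = subtree_species_names(ncbi, root_taxon_id, Rank.SPECIES)

    round_one = match_names(queries, references, fuzzy_threshold)
    by_query: dict[str, list[NameMatch]] = {q.taxon_id: [] for q in queries}
    for match in round_one:
        by_query[match.query.taxon_id].append(match)

    def has_real_match(candidates: list[NameMatch]) -> bool:
        return any(
            c.category in (MatchCategory.EXACT, MatchCategory.FUZZY) for c in candidates
        )

    unmatched = [q for q in queries if not has_real_match(by_query[q.taxon_id])]
    round_two = second_round_via_synonyms(unmatched, backbone, references, fuzzy_threshold)
    for match in round_two:
        if match.reference is not None:
            # second round only ever adds candidates for queries that had none
            by_query[match.query.taxon_id] = [
                c for c in by_query[match.query.taxon_id] if c.reference is None
            ]
            by_query[match.query.taxon_id].append(match)
    for candidates in by_query.values():
        for candidate in candidates:
            classify_match_authors(candidate)
    return kept, dropped, by_query


def run_linking(
    entries: Sequence[ChecklistEntry],
    backbone: TaxonStore,
    ncbi: TaxonStore,
    snapshot: WikidataSnapshot,
    root_taxon_id: str = "33090",
    fuzzy_threshold: int = 1,
    retrieved: datetime.date = datetime.date(2023, 1, 1),
    reference_kingdom: str = "",
) -> PipelineResult:
    """Run the full linking workflow on loaded stores."""
    kept, dropped, by_query = collect_candidates(
        entries, backbone, ncbi, root_taxon_id, fuzzy_threshold
    )
    all_matches: list[NameMatch] = []
    seen_queries: set[str] = set()
    cases: list[CurationCase] = []
    for entry, record in kept:
        candidates = by_query[record.taxon_id]
        if record.taxon_id not in seen_queries:
            seen_queries.add(record.taxon_id)
            all_matches.extend(candidates)
        real = [
            c
            for c in candidates
            if c.reference is not None
            and c.category in (MatchCategory.EXACT, MatchCategory.FUZZY)
        ]
        matched_ncbi = real[0].reference.taxon_id if real else ""
        evidence = gather_evidence(snapshot, entry.gbif_taxon_id, matched_ncbi)
        cases.append(
            assemble_case(entry, candidates, evidence, record.status, reference_kingdom)
        )

    flags = flag_homonyms(cases)
    summary = summarize(cases)
    statements_d: list[QuickStatement] = []
    statements_e: list[QuickStatement] = []
    for case in cases:
        if case.action is Action.D_BATCH_ADD_NCBI:
            statements_d.extend(statements_for_case(case, retrieved))
        elif case.action is Action.E_BATCH_UPDATE_GBIF:
            statements_e.extend(statements_for_case(case, retrieved))
    return PipelineResult(
        cases=cases,
        flags=flags,
        summary=summary,
        statements_add_ncbi=statements_d,
        statements_update_gbif=statements_e,
        dropped=dropped,
        matches=all_matches,
    )


def write_outputs(result: PipelineResult, output_dir: str | Path) -> dict[str, Path]:
    """Write all run outputs; returns the path of each artefact."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "curation": output_dir / "curation.tsv",
        "matches": output_dir / "matches.tsv",
        "qs_add_ncbi": output_dir / "qs_add_ncbi.txt",
        "qs_update_gbif": output_dir / "qs_update_gbif.txt",
        "summary": output_dir / "summary.tsv",
        "dropped": output_dir / "dropped.tsv",
        "homonym_flags": output_dir / "homonym_flags.tsv",
    }
    write_curation_table(result.cases, paths["curation"])
    write_matches(result.matches, paths["matches"])
    paths["qs_add_ncbi"].write_text(render(result.statements_add_ncbi), encoding="utf-8")
    paths["qs_update_gbif"].write_text(render(result.statements_update_gbif), encoding="utf-8")
    summary_lines = ["action\tcount"]
    for action in Action:
        summary_lines.append(f"{action.value}\t{result.summary[action]}")
    paths["summary"].write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
    dropped_lines = ["gbif_taxon_id\tsupplied_name\treason"]
    for entry, reason in result.dropped:
        dropped_lines.append(f"{entry.gbif_taxon_id}\t{entry.supplied_name}\t{reason}")
    paths["dropped"].write_text("\n".join(dropped_lines) + "\n", encoding="utf-8")
    flag_lines = ["gbif_taxon_id\tquery_author\treference_author\tkind"]
    for flag in result.flags:
        flag_lines.append(
            "\t".join(
                (
                    flag.case.entry.gbif_taxon_id,
                    flag.conflicting_authors[0],
                    flag.conflicting_authors[1],
                    flag.kind.value,
                )
            )
        )
    paths["homonym_flags"].write_text("\n".join(flag_lines) + "\n", encoding="utf-8")
    return paths


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file pipeline run; any stage failure raises with a
    stage-named message."""
    stages = {
        "read-species-list": lambda: read_species_list(config.species_list),
        "read-backbone": lambda: read_gbif_backbone(config.backbone),
        "read-taxdump": lambda: read_ncbi_taxdump(config.taxdump),
        "read-wikidata-snapshot": lambda: WikidataSnapshot.read(config.wikidata_snapshot),
    }
    loaded = {}
    for stage, loader in stages.items():
        try:
            loaded[stage] = loader()
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    try:
        result = run_linking(
            loaded["read-species-list"],
            loaded["read-backbone"],
            loaded["read-taxdump"],
            loaded["read-wikidata-snapshot"],
            root_taxon_id=config.root_taxon_id,
            fuzzy_threshold=config.fuzzy_threshold,
            retrieved=config.retrieved,
            reference_kingdom=config.reference_kingdom,
        )
    except Exception as exc:
        raise RuntimeError(f"stage linking failed: {exc}") from exc
    try:
        write_outputs(result, config.output_dir)
    except Exception as exc:
        raise RuntimeError(f"stage write-outputs failed: {exc}") from exc
    return result
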