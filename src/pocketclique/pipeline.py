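"""End-to-end scan: match a query against one or two template libraries.

Glue between the modules: clusters the library's ligand table, matches
every template, keeps the best-scoring record per template, ranks, and
assembles the combined ligand-site / catalytic-site report.  Budget-skipped
templates are collected and listed in the report footer, never silently
dropped.
"""

from __future__ import annotations

import logging

from . import __version__
from .clique_matcher import BudgetExceededError, match_template
from .config import RunConfig
from .ligand_clustering import ClusterTable, build_cluster_table
from .scoring import (
    MatchRecord,
    ScoredHit,
    combined_function_report,
    rank_hits,
)
from .structure_model import QueryStructure
from .template_library import FORMAT_VERSION, TemplateLibrary

logger = logging.getLogger(__name__)


def match_library(
    query: QueryStructure,
    library: TemplateLibrary,
    config: RunConfig,
) -> tuple[list[MatchRecord], list[str]]:
    """Match every library template; returns (records, skipped template ids)."""
    records: list[MatchRecord] = []
    skipped: list[str] = []
    for template in library.entries:
        try:
            records.extend(match_template(template, query, config.match_params))
        except BudgetExceededError as exc:
            logger.warning("skipping template: %s", exc)
            skipped.append(f"{template.template_id}: {exc}")
    return records, skipped


def _best_per_template(hits: list[ScoredHit]) -> list[ScoredHit]:
    """Keep each template's best hit (hits arrive ranked), re-ranking 1..n."""
    seen: set[str] = set()
    out = []
    for h in hits:
        if h.match.template_id in seen:
            continue
        seen.add(h.match.template_id)
        out.append(
            ScoredHit(
                match=h.match,
                ligand_code=h.ligand_code,
                cluster_rel_size=h.cluster_rel_size,
                coverage=h.coverage,
                score=h.score,
                rank=len(out) + 1,
            )
        )
    return out


def scan(
    query: QueryStructure,
    library: TemplateLibrary,
    config: RunConfig = RunConfig(),
    catalytic_library: TemplateLibrary | None = None,
    cluster_table: ClusterTable | None = None,
) -> dict:
    """Run the full pipeline and return the combined report (JSON-able dict).

    ``library`` supplies ligand-binding templates; an optional
    ``catalytic_library`` is scanned in the same pass so the report carries
    both the binding-site and the catalytic-activity view.  A precomputed
    ``cluster_table`` may be supplied; otherwise the library's own ligand
    table is clustered.
    """
    if not library.entries and (catalytic_library is None or not catalytic_library.entries):
        raise ValueError("no templates to scan against")

    if cluster_table is None:
        cluster_table = build_cluster_table(
            library.ligand_table,
            sim_threshold=config.sim_threshold,
            backend=config.fingerprint_backend,
            norm=config.cluster_norm,
        )

    lig_records, skipped = match_library(query, library, config)
    lig_hits = _best_per_template(
        rank_hits(lig_records, cluster_table, config.score_weights)
    )

    cat_hits: list[ScoredHit] = []
    if catalytic_library is not None:
        cat_records, cat_skipped = match_library(query, catalytic_library, config)
        skipped += cat_skipped
        cat_hits = _best_per_template(
            rank_hits(cat_records, None, config.score_weights)
        )

    metadata = {
        "tool_version": __version__,
        "config_hash": config.config_hash,
        "library_format_version": FORMAT_VERSION,
        "fingerprint_backend": cluster_table.backend,
        "query_id": query.structure_id,
        "n_query_residues": len(query.residues),
        "n_templates": len(library.entries)
        + (len(catalytic_library.entries) if catalytic_library else 0),
    }
    return combined_function_report(
        lig_hits,
        cat_hits,
        top_k=config.top_k,
        metadata=metadata,
        skipped_templates=skipped,
    )
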