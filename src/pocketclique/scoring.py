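"""Composite scoring and ranking of site matches.

Each match contributes three signals: how much of the template was
recovered (clique size over template size), how well the matched residues
superpose (RMSD), and how chemically common the template's ligand is (the
relative size of its SMILES-similarity cluster).  The default composite
score is

    S = w_c · (clique_size / template_size) + w_r · exp(−RMSD / ρ) + w_l · rel_size

with defaults w_c = w_r = 1, w_l = 0.5 and ρ = 1.5 Å, so S ∈ [0, 2.5] for
ligand-site hits.  Catalytic-site templates have no ligand: their ligand
term is 0 and their score range is [0, w_c + w_r].  The formula is a
bounded, monotone combination — strictly increasing in clique size and
cluster size, strictly decreasing in RMSD — and every weight is exposed in
configuration so an alternative combination can be dropped in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .clique_matcher import CliqueCorrespondence
    from .ligand_clustering import ClusterTable
    from .superposition import RigidTransform

SCHEMA_NAME = "pocketclique-report"
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite score (all non-negative; ρ in Å, positive)."""

    w_clique: float = 1.0
    w_rmsd: float = 1.0
    w_ligand: float = 0.5
    rmsd_scale: float = 1.5

    def __post_init__(self) -> None:
        if min(self.w_clique, self.w_rmsd, self.w_ligand) < 0:
            raise ValueError("score weights must be non-negative")
        if self.rmsd_scale <= 0:
            raise ValueError("rmsd_scale must be positive")

    @property
    def max_score(self) -> float:
        return self.w_clique + self.w_rmsd + self.w_ligand


@dataclass(frozen=True, eq=False)
class MatchRecord:
    """One template↔query correspondence with its superposition."""

    template_id: str
    source_structure: str
    site_kind: str
    ligand_code: str
    correspondence: "CliqueCorrespondence"
    transform: "RigidTransform"
    rmsd: float
    clique_size: int
    template_size: int
    spans_chains: frozenset[str]
    matched_query_residues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 3 <= self.clique_size <= self.template_size:
            raise ValueError(
                f"clique_size {self.clique_size} outside [3, {self.template_size}]"
            )
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass(frozen=True, eq=False)
class ScoredHit:
    """A ranked match: MatchRecord plus its composite score."""

    match: MatchRecord
    ligand_code: str
    cluster_rel_size: float | None
    coverage: float
    score: float
    rank: int


def composite_score(
    clique_size: int,
    template_size: int,
    rmsd: float,
    cluster_rel_size: float | None,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Combine clique coverage, RMSD and ligand-cluster weight into one score.

    ``cluster_rel_size=None`` marks a ligand-less (catalytic) hit: the
    ligand term is dropped.  Inputs outside their invariant ranges raise
    ``ValueError``.
    """
    if not 3 <= clique_size <= template_size:
        raise ValueError(
            f"clique_size {clique_size} outside [3, template_size={template_size}]"
        )
    if not rmsd >= 0:
        raise ValueError(f"rmsd {rmsd} must be >= 0")
    if cluster_rel_size is not None and not 0.0 < cluster_rel_size <= 1.0:
        raise ValueError(f"cluster_rel_size {cluster_rel_size} outside (0, 1]")
    coverage = clique_size / template_size
    score = weights.w_clique * coverage + weights.w_rmsd * math.exp(
        -rmsd / weights.rmsd_scale
    )
    if cluster_rel_size is not None:
        score += weights.w_ligand * cluster_rel_size
    return score


def rank_hits(
    matches: Sequence[MatchRecord],
    clusters: "ClusterTable | None" = None,
    weights: ScoreWeights = ScoreWeights(),
) -> list[ScoredHit]:
    """Score every match and return hits sorted and ranked.

    Order: score descending, ties broken by (RMSD ascending, clique size
    descending, template_id ascending, matched residues) — a total order,
    so the output is invariant under permutation of ``matches``.  Ranks are
    1-based positions in that order.  Ligand hits with no cluster table (or
    a code missing from it) fall back to the table's singleton weight, or
    1.0 when no table exists at all.
    """
    hits = []
    for m in matches:
        if m.site_kind == "catalytic" or not m.ligand_code:
            rel: float | None = None
        elif clusters is None:
            rel = 1.0
        else:
            rel = clusters.rel_size(m.ligand_code)
        score = composite_score(m.clique_size, m.template_size, m.rmsd, rel, weights)
        hits.append((score, m, rel))
    hits.sort(
        key=lambda t: (
            -t[0],
            t[1].rmsd,
            -t[1].clique_size,
            t[1].template_id,
            t[1].matched_query_residues,
        )
    )
    return [
        ScoredHit(
            match=m,
            ligand_code=m.ligand_code,
            cluster_rel_size=rel,
            coverage=m.clique_size / m.template_size,
            score=score,
            rank=i + 1,
        )
        for i, (score, m, rel) in enumerate(hits)
    ]


def _hit_to_dict(hit: ScoredHit) -> dict:
    m = hit.match
    return {
        "rank": hit.rank,
        "template_id": m.template_id,
        "source_structure": m.source_structure,
        "ligand_code": m.ligand_code,
        "clique_size": m.clique_size,
        "template_size": m.template_size,
        "rmsd": round(m.rmsd, 6),
        "cluster_rel_size": (
            None if hit.cluster_rel_size is None else round(hit.cluster_rel_size, 6)
        ),
        "score": round(hit.score, 6),
        "chains": "+".join(sorted(m.spans_chains)),
        "matched_residues": list(m.matched_query_residues),
    }


def combined_function_report(
    ligand_hits: Sequence[ScoredHit],
    catalytic_hits: Sequence[ScoredHit],
    top_k: int = 10,
    metadata: Mapping | None = None,
    skipped_templates: Sequence[str] = (),
) -> dict:
    """Merge ranked ligand-site and catalytic-site hits into one report.

    Both sections are truncated to ``top_k``; empty sections are reported
    explicitly ("no hits") rather than omitted, so a combined run always
    shows both the binding-site and the catalytic-activity view.
    """
    def section(hits: Sequence[ScoredHit]) -> dict:
        return {
            "n_hits": len(hits),
            "note": "no hits" if not hits else "",
            "hits": [_hit_to_dict(h) for h in hits[:top_k]],
        }

    return {
        "schema": {"name": SCHEMA_NAME, "version": SCHEMA_VERSION},
        "metadata": dict(metadata or {}),
        "ligand_sites": section(ligand_hits),
        "catalytic_sites": section(catalytic_hits),
        "skipped_templates": list(skipped_templates),
    }


TSV_COLUMNS = (
    "section", "rank", "template_id", "source_structure", "ligand_code",
    "clique_size", "template_size", "rmsd", "cluster_rel_size", "score",
    "chains", "matched_residues",
)


def report_to_tsv(report: Mapping) -> str:
    """Flatten a combined report to TSV (metadata as ``#`` comment lines)."""
    lines = []
    meta = report.get("metadata", {})
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    lines.append("\t".join(TSV_COLUMNS))
    for section_name in ("ligand_sites", "catalytic_sites"):
        for hit in report.get(section_name, {}).get("hits", []):
            row = [section_name]
            for col in TSV_COLUMNS[1:]:
                val = hit[col]
                if col == "matched_residues":
                    val = ";".join(val)
                elif val is None:
                    val = "NA"
                elif isinstance(val, float):
                    val = f"{val:.6f}"
                row.append(str(val))
            lines.append("\t".join(row))
    for skipped in report.get("skipped_templates", []):
        lines.append(f"# skipped: {skipped}")
    return "\n".join(lines) + "\n"


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
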