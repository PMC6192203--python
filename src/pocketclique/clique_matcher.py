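"""Association-graph construction and maximum-clique site matching.

A template is matched against a query through their product ("association")
graph: a vertex is a compatible (template residue, query residue) pair, and
two vertices are joined by an edge when the template-side and query-side
pairwise distances agree within a tolerance — for both the Cα–Cα and the
side-chain-centroid distances.  Every clique in this graph is therefore a
geometrically self-consistent residue correspondence, and maximal cliques
are candidate site placements.

Cliques are enumerated with Bron–Kerbosch (pivoting, degeneracy ordering)
over bitset adjacency.  Output ordering is fully deterministic: cliques are
sorted by size (largest first), then lexicographically on their sorted
vertex pairs.  Clique enumeration is worst-case exponential, so graphs
whose edge count exceeds a configurable budget are rejected loudly
(:class:`BudgetExceededError`) rather than searched partially.

Interface mode: by default the graph is built for one query chain at a
time, so a correspondence never crosses chains.  With ``interface_mode``
the graph is built over all chains jointly and a clique may span subunits,
which is how sites at inter-chain interfaces are detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .scoring import MatchRecord
from .structure_model import QueryStructure
from .superposition import correspondence_rmsd
from .template_library import SiteTemplate

logger = logging.getLogger(__name__)

AA_MODES = ("strict", "relaxed")

#: physicochemical groups used by the relaxed residue-compatibility mode
RELAXED_GROUPS: tuple[frozenset[str], ...] = (
    frozenset(["ASP", "GLU"]),
    frozenset(["LYS", "ARG", "HIS"]),
    frozenset(["SER", "THR"]),
    frozenset(["ILE", "LEU", "VAL", "MET"]),
    frozenset(["PHE", "TYR", "TRP"]),
    frozenset(["ASN", "GLN"]),
    frozenset(["ALA", "GLY"]),
    frozenset(["CYS"]),
    frozenset(["PRO"]),
)

_GROUP_OF: dict[str, int] = {
    aa: gi for gi, group in enumerate(RELAXED_GROUPS) for aa in group
}

DEFAULT_DIST_TOL = 1.5
DEFAULT_MIN_CLIQUE_SIZE = 3
DEFAULT_RMSD_CUTOFF = 3.0
DEFAULT_EDGE_BUDGET = 200_000
DEFAULT_MAX_CLIQUES = 100


class BudgetExceededError(Exception):
    """The association graph is too large to enumerate cliques exactly.

    Raised instead of truncating silently; the caller should skip the
    template and record the skip.
    """

    def __init__(self, label: str, n_vertices: int, n_edges: int, budget: int):
        self.label = label
        self.n_vertices = n_vertices
        self.n_edges = n_edges
        self.budget = budget
        super().__init__(
            f"association graph for {label!r} has {n_edges} edges "
            f"({n_vertices} vertices), exceeding the budget of {budget}"
        )


def aa_compatible(aa_t: str, aa_q: str, aa_mode: str = "strict") -> bool:
    """Residue-type compatibility between a template and a query residue."""
    if aa_mode == "strict":
        return aa_t == aa_q
    if aa_mode == "relaxed":
        return _GROUP_OF.get(aa_t, -1) == _GROUP_OF.get(aa_q, -2)
    raise ValueError(f"unknown aa_mode {aa_mode!r}; expected one of {AA_MODES}")


@dataclass(frozen=True)
class AssociationGraph:
    """Product graph of compatible residue pairs.

    ``vertices[v]`` is the pair (template index, query index); ``adjacency[v]``
    is a bitmask over vertex indices (bit ``u`` set ⇔ edge v–u).
    """

    vertices: tuple[tuple[int, int], ...]
    adjacency: tuple[int, ...]
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(a.bit_count() for a in self.adjacency) // 2

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.adjacency[u] >> v & 1)

    def edges(self) -> set[tuple[int, int]]:
        """Edge set as sorted index pairs (for oracles/inspection)."""
        out = set()
        for u, bits in enumerate(self.adjacency):
            m = bits >> (u + 1) << (u + 1)  # neighbours above u
            while m:
                v = (m & -m).bit_length() - 1
                out.add((u, v))
                m &= m - 1
        return out

    @classmethod
    def from_edges(
        cls,
        vertices: Sequence[tuple[int, int]],
        edges: Sequence[tuple[int, int]],
        params: Mapping[str, object] | None = None,
    ) -> "AssociationGraph":
        """Build a graph directly from an explicit edge list (used in tests)."""
        adj = [0] * len(vertices)
        for u, v in edges:
            if u == v:
                raise ValueError("self-loops are not allowed")
            adj[u] |= 1 << v
            adj[v] |= 1 << u
        return cls(tuple(tuple(p) for p in vertices), tuple(adj), params or {})


@dataclass(frozen=True)
class CliqueCorrespondence:
    """A clique of the association graph: an injective residue correspondence.

    ``pairs`` are (template residue index, query residue index), sorted by
    template index; indices refer to the template/query passed to matching.
    """

    pairs: tuple[tuple[int, int], ...]
    spans_chains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        t_side = [p[0] for p in self.pairs]
        q_side = [p[1] for p in self.pairs]
        if len(set(t_side)) != len(t_side) or len(set(q_side)) != len(q_side):
            raise ValueError("correspondence must be injective on both sides")

    @property
    def size(self) -> int:
        return len(self.pairs)


def build_association_graph(
    template: SiteTemplate,
    query: QueryStructure,
    dist_tol: float = DEFAULT_DIST_TOL,
    aa_mode: str = "strict",
) -> AssociationGraph:
    """Build the template×query association graph.

    Vertex (i, j) exists iff residue types are compatible under ``aa_mode``.
    Edge ((i, j), (k, l)) exists iff i≠k, j≠l and both pseudo-atom distance
    differences, |d_Cα(tᵢ,tₖ) − d_Cα(qⱼ,qₗ)| and |d_sc(tᵢ,tₖ) − d_sc(qⱼ,qₗ)|,
    are ≤ ``dist_tol`` Å.  An empty graph is a valid result.
    """
    if aa_mode not in AA_MODES:
        raise ValueError(f"unknown aa_mode {aa_mode!r}; expected one of {AA_MODES}")
    t_aa = [r.aa_type for r in template.residues]
    q_aa = [r.aa_type for r in query.residues]
    vertices = [
        (i, j)
        for i in range(len(t_aa))
        for j in range(len(q_aa))
        if aa_compatible(t_aa[i], q_aa[j], aa_mode)
    ]
    params = {
        "template_id": template.template_id,
        "dist_tol": float(dist_tol),
        "aa_mode": aa_mode,
    }
    if not vertices:
        return AssociationGraph((), (), params)

    t_ca = np.array([r.ca_coord for r in template.residues])
    t_sc = np.array([r.sc_centroid for r in template.residues])
    q_ca = query.ca_array()
    q_sc = query.sc_array()

    def dmat(x: np.ndarray) -> np.ndarray:
        d = x[:, None, :] - x[None, :, :]
        return np.sqrt((d**2).sum(axis=2))

    Dt_ca, Dt_sc, Dq_ca, Dq_sc = dmat(t_ca), dmat(t_sc), dmat(q_ca), dmat(q_sc)

    ti = np.array([v[0] for v in vertices])
    qj = np.array([v[1] for v in vertices])
    ok = (
        (ti[:, None] != ti[None, :])
        & (qj[:, None] != qj[None, :])
        & (np.abs(Dt_ca[np.ix_(ti, ti)] - Dq_ca[np.ix_(qj, qj)]) <= dist_tol)
        & (np.abs(Dt_sc[np.ix_(ti, ti)] - Dq_sc[np.ix_(qj, qj)]) <= dist_tol)
    )
    np.fill_diagonal(ok, False)
    adjacency = []
    for row in ok:
        bits = 0
        for v in np.flatnonzero(row):
            bits |= 1 << int(v)
        adjacency.append(bits)
    return AssociationGraph(tuple(vertices), tuple(adjacency), params)


def _degeneracy_order(adj: Sequence[int], n: int) -> list[int]:
    """Vertex ordering by repeated minimum-degree removal."""
    degree = [a.bit_count() for a in adj]
    removed = 0
    order = []
    for _ in range(n):
        v = min(
            (i for i in range(n) if not removed >> i & 1),
            key=lambda i: (degree[i], i),
        )
        order.append(v)
        removed |= 1 << v
        m = adj[v] & ~removed
        while m:
            u = (m & -m).bit_length() - 1
            degree[u] -= 1
            m &= m - 1
    return order


def _bron_kerbosch_pivot(adj: Sequence[int], R: int, P: int, X: int, out: list[int]) -> None:
    if P == 0 and X == 0:
        out.append(R)
        return
    # pivot: vertex of P ∪ X with most neighbours in P
    best_u, best_cover = -1, -1
    m = P | X
    while m:
        u = (m & -m).bit_length() - 1
        cover = (P & adj[u]).bit_count()
        if cover > best_cover:
            best_u, best_cover = u, cover
        m &= m - 1
    cand = P & ~adj[best_u]
    while cand:
        vbit = cand & -cand
        v = vbit.bit_length() - 1
        _bron_kerbosch_pivot(adj, R | vbit, P & adj[v], X & adj[v], out)
        P &= ~vbit
        X |= vbit
        cand &= cand - 1


def _all_maximal_cliques(adj: Sequence[int], n: int) -> list[int]:
    """All maximal cliques as bitmasks (Bron–Kerbosch, degeneracy outer loop)."""
    if n == 0:
        return []
    order = _degeneracy_order(adj, n)
    pos = {v: i for i, v in enumerate(order)}
    out: list[int] = []
    for v in order:
        later = 0
        earlier = 0
        m = adj[v]
        while m:
            u = (m & -m).bit_length() - 1
            if pos[u] > pos[v]:
                later |= 1 << u
            else:
                earlier |= 1 << u
            m &= m - 1
        _bron_kerbosch_pivot(adj, 1 << v, later, earlier, out)
    return out


def find_max_cliques(
    graph: AssociationGraph,
    min_clique_size: int = DEFAULT_MIN_CLIQUE_SIZE,
    max_results: int = DEFAULT_MAX_CLIQUES,
    edge_budget: int = DEFAULT_EDGE_BUDGET,
) -> list[CliqueCorrespondence]:
    """All maximal cliques of size ≥ ``min_clique_size``, largest first.

    Ordering is deterministic: size descending, then lexicographic on the
    sorted vertex-pair lists; the list is truncated to ``max_results``.
    Raises :class:`BudgetExceededError` when the graph exceeds
    ``edge_budget`` edges (the caller should skip, never truncate).
    """
    n_edges = graph.n_edges
    if n_edges > edge_budget:
        raise BudgetExceededError(
            str(graph.params.get("template_id", "<graph>")),
            graph.n_vertices,
            n_edges,
            edge_budget,
        )
    cliques = []
    for bits in _all_maximal_cliques(graph.adjacency, graph.n_vertices):
        members = []
        m = bits
        while m:
            v = (m & -m).bit_length() - 1
            members.append(graph.vertices[v])
            m &= m - 1
        if len(members) < min_clique_size:
            continue
        cliques.append(tuple(sorted(members)))
    cliques.sort(key=lambda pairs: (-len(pairs), pairs))
    return [CliqueCorrespondence(pairs=p) for p in cliques[:max_results]]


@dataclass(frozen=True)
class MatchParams:
    """Tunables for template→query matching."""

    dist_tol: float = DEFAULT_DIST_TOL
    min_clique_size: int = DEFAULT_MIN_CLIQUE_SIZE
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
    aa_mode: str = "strict"
    interface_mode: bool = False
    edge_budget: int = DEFAULT_EDGE_BUDGET
    max_cliques: int = DEFAULT_MAX_CLIQUES


def match_template(
    template: SiteTemplate,
    query: QueryStructure,
    params: MatchParams = MatchParams(),
) -> list[MatchRecord]:
    """Match one template against a query structure.

    Composes graph construction → maximal-clique enumeration → rigid
    superposition; correspondences whose RMSD exceeds
    ``params.rmsd_cutoff`` are discarded.  Without ``interface_mode`` the
    graph is built per query chain; with it, one joint graph lets a
    correspondence span chains.  Raises :class:`BudgetExceededError` (for
    the caller to record as a skipped template).
    """
    if params.interface_mode:
        chain_groups: list[Sequence[str]] = [sorted(query.chain_ids)]
    else:
        chain_groups = [[c] for c in sorted(query.chain_ids)]

    records: list[MatchRecord] = []
    for chains in chain_groups:
        sub, idx_map = query.subset(chains)
        if not sub.residues:
            continue
        graph = build_association_graph(
            template, sub, dist_tol=params.dist_tol, aa_mode=params.aa_mode
        )
        cliques = find_max_cliques(
            graph,
            min_clique_size=params.min_clique_size,
            max_results=params.max_cliques,
            edge_budget=params.edge_budget,
        )
        for corr in cliques:
            global_pairs = tuple(
                sorted((ti, idx_map[qj]) for ti, qj in corr.pairs)
            )
            spans = frozenset(query.residues[qj].chain_id for _, qj in global_pairs)
            gcorr = CliqueCorrespondence(pairs=global_pairs, spans_chains=spans)
            transform, rmsd = correspondence_rmsd(gcorr, template, query)
            if rmsd > params.rmsd_cutoff:
                continue
            records.append(
                MatchRecord(
                    template_id=template.template_id,
                    source_structure=template.source_structure,
                    site_kind=template.site_kind,
                    ligand_code=template.ligand_code,
                    correspondence=gcorr,
                    transform=transform,
                    rmsd=rmsd,
                    clique_size=gcorr.size,
                    template_size=len(template.residues),
                    spans_chains=spans,
                    matched_query_residues=tuple(
                        query.residues[qj].label for _, qj in global_pairs
                    ),
                )
            )
    records.sort(key=lambda r: (-r.clique_size, r.rmsd, r.correspondence.pairs))
    return records
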