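"""Association graph, maximal-clique enumeration and template matching."""

import itertools

import numpy as np
import pytest

from pocketclique.clique_matcher import (
    AssociationGraph,
    BudgetExceededError,
    CliqueCorrespondence,
    MatchParams,
    aa_compatible,
    build_association_graph,
    find_max_cliques,
    match_template,
)
from pocketclique.fixtures import (
    PlantedSiteSpec,
    generate_decoy_library,
    generate_planted_structure,
)
from pocketclique.structure_model import QueryStructure, parse_pdb_text
from pocketclique.template_library import SiteTemplate

from conftest import brute_force_maximal_cliques, random_association_graph


def template_as_query(template: SiteTemplate) -> QueryStructure:
    return QueryStructure(template.source_structure, template.residues)


@pytest.fixture(scope="module")
def template6():
    return generate_decoy_library(1, sizes=(6, 6), seed=11).entries[0]


class TestAaCompatibility:
    def test_strict_is_identity(self):
        assert aa_compatible("ASP", "ASP", "strict")
        assert not aa_compatible("ASP", "GLU", "strict")

    def test_relaxed_groups(self):
        assert aa_compatible("ASP", "GLU", "relaxed")
        assert aa_compatible("LYS", "HIS", "relaxed")
        assert not aa_compatible("ASP", "LYS", "relaxed")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            aa_compatible("ASP", "ASP", "fuzzy")


class TestBuildAssociationGraph:
    def test_self_match_contains_identity_clique(self, template6):
        g = build_association_graph(template6, template_as_query(template6))
        identity = [(i, i) for i in range(len(template6.residues))]
        vmap = {v: k for k, v in enumerate(g.vertices)}
        ids = [vmap[p] for p in identity]
        for u, v in itertools.combinations(ids, 2):
            assert g.has_edge(u, v)

    def test_no_compatible_residue_types_gives_empty_graph(self, template6):
        aa = "GLY" if "GLY" not in {r.aa_type for r in template6.residues} else "CYS"
        query = QueryStructure(
            "q",
            tuple(
                r.__class__(**{**r.__dict__, "aa_type": aa})
                for r in template6.residues
            ),
        )
        g = build_association_graph(template6, query)
        assert g.n_vertices == 0 and g.n_edges == 0

    def test_edges_match_brute_force_checker(self, template6):
        """Every vertex pair is checked against an O(V²) distance oracle."""
        pdb, planted = generate_planted_structure(
            PlantedSiteSpec(n_site_residues=4, noise_sigma=0.4,
                            n_decoy_residues=6, seed=9)
        )
        query = parse_pdb_text(pdb)
        tol = 1.5
        g = build_association_graph(planted, query, dist_tol=tol)

        def dist(a, b):
            return float(np.linalg.norm(np.array(a) - np.array(b)))

        expected = set()
        for u, v in itertools.combinations(range(g.n_vertices), 2):
            (i, j), (k, l) = g.vertices[u], g.vertices[v]
            if i == k or j == l:
                continue
            t_i, t_k = planted.residues[i], planted.residues[k]
            q_j, q_l = query.residues[j], query.residues[l]
            if (
                abs(dist(t_i.ca_coord, t_k.ca_coord)
                    - dist(q_j.ca_coord, q_l.ca_coord)) <= tol
                and abs(dist(t_i.sc_centroid, t_k.sc_centroid)
                        - dist(q_j.sc_centroid, q_l.sc_centroid)) <= tol
            ):
                expected.add((u, v))
        assert g.edges() == expected

    def test_edge_test_symmetric(self, template6):
        g = build_association_graph(template6, template_as_query(template6))
        for u in range(g.n_vertices):
            for v in range(g.n_vertices):
                assert g.has_edge(u, v) == g.has_edge(v, u)

    def test_edge_set_monotone_in_dist_tol(self, template6):
        pdb, planted = generate_planted_structure(
            PlantedSiteSpec(n_site_residues=5, noise_sigma=0.5,
                            n_decoy_residues=10, seed=21)
        )
        query = parse_pdb_text(pdb)
        e_tight = build_association_graph(planted, query, dist_tol=0.5).edges()
        e_mid = build_association_graph(planted, query, dist_tol=1.5).edges()
        e_loose = build_association_graph(planted, query, dist_tol=3.0).edges()
        assert e_tight <= e_mid <= e_loose


class TestFindMaxCliques:
    def test_complete_graph_one_clique(self):
        vertices = [(i, i) for i in range(5)]
        edges = list(itertools.combinations(range(5), 2))
        g = AssociationGraph.from_edges(vertices, edges)
        cliques = find_max_cliques(g, min_clique_size=3)
        assert len(cliques) == 1
        assert cliques[0].size == 5

    def test_two_disjoint_triangles(self):
        vertices = [(i, i) for i in range(6)]
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        g = AssociationGraph.from_edges(vertices, edges)
        cliques = find_max_cliques(g, min_clique_size=3)
        assert [c.size for c in cliques] == [3, 3]

    def test_min_size_filters(self):
        vertices = [(i, i) for i in range(4)]
        g = AssociationGraph.from_edges(vertices, [(0, 1)])
        assert find_max_cliques(g, min_clique_size=3) == []

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        """Random ≤15-vertex graphs: clique set equals subset enumeration."""
        rng = np.random.default_rng(seed)
        g, edges = random_association_graph(rng)
        found = {
            frozenset(
                g.vertices.index(p) for p in c.pairs
            )
            for c in find_max_cliques(g, min_clique_size=1, max_results=10**6)
        }
        assert found == brute_force_maximal_cliques(list(g.vertices), edges)

    def test_agrees_with_networkx(self):
        """Independent Bron–Kerbosch implementation finds the same cliques."""
        import networkx as nx

        rng = np.random.default_rng(77)
        for _ in range(20):
            g, edges = random_association_graph(rng)
            G = nx.Graph()
            G.add_nodes_from(range(g.n_vertices))
            G.add_edges_from(edges)
            expected = {frozenset(c) for c in nx.find_cliques(G)}
            found = {
                frozenset(g.vertices.index(p) for p in c.pairs)
                for c in find_max_cliques(g, min_clique_size=1, max_results=10**6)
            }
            assert found == expected

    def test_deterministic_ordering(self):
        vertices = [(i, i) for i in range(6)]
        edges = [(3, 4), (3, 5), (4, 5), (0, 1), (0, 2), (1, 2), (2, 3)]
        g = AssociationGraph.from_edges(vertices, edges)
        a = find_max_cliques(g, min_clique_size=2)
        b = find_max_cliques(g, min_clique_size=2)
        assert [c.pairs for c in a] == [c.pairs for c in b]
        sizes = [c.size for c in a]
        assert sizes == sorted(sizes, reverse=True)

    def test_budget_exceeded_raises(self, template6):
        g = build_association_graph(template6, template_as_query(template6))
        with pytest.raises(BudgetExceededError):
            find_max_cliques(g, edge_budget=1)

    def test_correspondence_injective(self):
        with pytest.raises(ValueError):
            CliqueCorrespondence(pairs=((0, 1), (0, 2)))


class TestMatchTemplate:
    def test_self_match_identity(self):
        """Every generated template matches its own source exactly."""
        for seed in range(10):
            lib = generate_decoy_library(1, sizes=(4, 8), seed=seed)
            t = lib.entries[0]
            records = match_template(t, template_as_query(t))
            assert records, f"no self-match for seed {seed}"
            best = records[0]
            assert best.clique_size == len(t.residues)
            assert best.rmsd <= 1e-6

    def test_single_chain_site_unaffected_by_interface_mode(self):
        pdb, planted = generate_planted_structure(
            PlantedSiteSpec(n_site_residues=5, noise_sigma=0.2,
                            n_decoy_residues=20, seed=4)
        )
        query = parse_pdb_text(pdb)
        on = match_template(planted, query, MatchParams(interface_mode=True))
        off = match_template(planted, query, MatchParams(interface_mode=False))
        assert [r.correspondence.pairs for r in on] == [
            r.correspondence.pairs for r in off
        ]

    def test_split_site_needs_interface_mode(self):
        """A 3+2 split across chains is found only with interface mode on."""
        spec = PlantedSiteSpec(
            n_site_residues=5, noise_sigma=0.3, n_decoy_residues=30,
            split_across_chains=(2, (3, 2)), seed=13,
        )
        pdb, planted = generate_planted_structure(spec)
        query = parse_pdb_text(pdb)
        on = match_template(
            planted, query, MatchParams(min_clique_size=5, interface_mode=True)
        )
        off = match_template(
            planted, query, MatchParams(min_clique_size=5, interface_mode=False)
        )
        assert on and not off
        assert on[0].spans_chains == {"A", "B"}

    def test_decoy_negative_control(self):
        """Templates never sit well on unrelated decoy geometry (Monte Carlo)."""
        lib = generate_decoy_library(1, sizes=(6, 6), seed=100)
        template = lib.entries[0]
        good_rmsd = 0
        trials = 30
        for seed in range(trials):
            pdb, _ = generate_planted_structure(
                PlantedSiteSpec(n_site_residues=6, noise_sigma=0.0,
                                n_decoy_residues=0, seed=1000 + seed)
            )
            decoy_query = parse_pdb_text(pdb)
            records = match_template(
                template, decoy_query, MatchParams(rmsd_cutoff=np.inf)
            )
            if any(
                r.rmsd <= 2.0 and r.clique_size >= 4 for r in records
            ):
                good_rmsd += 1
        assert good_rmsd <= max(1, trials // 20)

    def test_budget_skip_propagates(self, template6):
        q = template_as_query(template6)
        with pytest.raises(BudgetExceededError):
            match_template(template6, q, MatchParams(edge_budget=1))
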