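"""Shared hand-written structure fixtures and oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

# --------------------------------------------------------------------------
# hand-written PDB texts (coordinates chosen so expected values are
# hand-computable; see individual tests)

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -1.000   1.000  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.000   1.500   0.000  1.00  0.00           O
ATOM     10  N   LYS A   3       6.200   3.700   0.000  1.00  0.00           N
ATOM     11  CA  LYS A   3       7.650   3.700   0.000  1.00  0.00           C
ATOM     12  CB  LYS A   3       8.200   5.100   0.200  1.00  0.00           C
ATOM     13  CG  LYS A   3       9.700   5.100   0.400  1.00  0.00           C
ATOM     14  CD  LYS A   3      10.300   6.500   0.400  1.00  0.00           C
ATOM     15  CE  LYS A   3      11.800   6.500   0.600  1.00  0.00           C
ATOM     16  NZ  LYS A   3      12.400   7.800   0.600  1.00  0.00           N
HETATM   17  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""

#: LYS side-chain heavy atoms: CB, CG, CD, CE, NZ (hand mean below)
LYS_SC_CENTROID = (
    (8.200 + 9.700 + 10.300 + 11.800 + 12.400) / 5,
    (5.100 + 5.100 + 6.500 + 6.500 + 7.800) / 5,
    (0.200 + 0.400 + 0.400 + 0.600 + 0.600) / 5,
)

# ALA residue with an altloc pair: conformer A has occupancy 0.60,
# conformer B 0.40 — parsing must keep the A atoms.
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      4  CB AALA A   1       1.000   1.500   0.000  0.60  0.00           C
ATOM      5  CB BALA A   1       2.000   1.500   0.000  0.40  0.00           C
ATOM      6  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      7  CA  GLY A   3       8.000   0.000   0.000  1.00  0.00           C
END
"""

# MSE (selenomethionine) must be parsed and remapped to MET; the UNK
# residue must be dropped.
NONSTANDARD_PDB = """\
ATOM      1  CA  MSE A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  MSE A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA  UNK A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   3      10.000   0.000   0.000  1.00  0.00           C
ATOM      5  CB  ALA A   3      11.500   0.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY A   4      15.000   0.000   0.000  1.00  0.00           C
END
"""

# Single-atom ligand at the origin; 5 residues with Cα at 3 Å (contacts at
# cutoff 4.0) and 5 at 12 Å (never contacts).  Side-chain CB points outward.
CONTACT_PDB_NEAR = [(3, 0, 0), (0, 3, 0), (0, 0, 3), (-3, 0, 0), (0, -3, 0)]
CONTACT_PDB_FAR = [(12, 0, 0), (0, 12, 0), (0, 0, 12), (-12, 0, 0), (0, -12, 0)]


def _contact_pdb() -> str:
    lines = []
    serial = 1
    for seq, ca in enumerate(CONTACT_PDB_NEAR + CONTACT_PDB_FAR, start=1):
        ca = np.array(ca, dtype=float)
        cb = ca * (1 + 1.5 / np.linalg.norm(ca))
        for name, xyz in (("CA", ca), ("CB", cb)):
            lines.append(
                f"ATOM  {serial:>5}  {name:<3} ALA A{seq:>4}    "
                f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}  1.00  0.00"
                f"           C"
            )
            serial += 1
    lines.append(
        f"HETATM{serial:>5}  C1  XYZ A 900       0.000   0.000   0.000"
        f"  1.00  0.00           C"
    )
    lines.append("END")
    return "\n".join(lines) + "\n"


CONTACT_PDB = _contact_pdb()


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def contact_pdb(tmp_path):
    p = tmp_path / "holo.pdb"
    p.write_text(CONTACT_PDB)
    return p


# --------------------------------------------------------------------------
# independent oracles

def brute_force_maximal_cliques(
    vertices: list, edges: set[tuple[int, int]]
) -> set[frozenset[int]]:
    """Exhaustive subset-enumeration maximal-clique oracle (graphs ≤ ~16 v)."""
    n = len(vertices)
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def is_clique(sub: tuple[int, ...]) -> bool:
        return all(v in adj[u] for u, v in itertools.combinations(sub, 2))

    cliques = [
        set(sub)
        for r in range(1, n + 1)
        for sub in itertools.combinations(range(n), r)
        if is_clique(sub)
    ]
    maximal = set()
    for c in cliques:
        if not any(c < other for other in cliques):
            maximal.add(frozenset(c))
    return maximal


def random_association_graph(rng: np.random.Generator, max_vertices: int = 15):
    """Random graph respecting the association-graph vertex/edge invariants."""
    from pocketclique.clique_matcher import AssociationGraph

    nt = int(rng.integers(2, 6))
    nq = int(rng.integers(2, 7))
    all_pairs = [(i, j) for i in range(nt) for j in range(nq)]
    rng.shuffle(all_pairs)
    n = int(rng.integers(1, min(max_vertices, len(all_pairs)) + 1))
    vertices = sorted(all_pairs[:n])
    edges = set()
    for u, v in itertools.combinations(range(len(vertices)), 2):
        (i, j), (k, l) = vertices[u], vertices[v]
        if i != k and j != l and rng.random() < 0.4:
            edges.add((u, v))
    return AssociationGraph.from_edges(vertices, sorted(edges)), edges


def grid_search_rmsd(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Brute-force rotation-grid superposition RMSD (zooming Euler grid)."""
    from scipy.spatial.transform import Rotation

    F = fixed - fixed.mean(axis=0)
    M = moving - moving.mean(axis=0)

    def rmsd_for(rotmats: np.ndarray) -> np.ndarray:
        moved = np.einsum("rij,nj->rni", rotmats, M)
        return np.sqrt(((moved - F[None]) ** 2).sum(axis=(1, 2)) / F.shape[0])

    centers = np.array([0.0, 0.0, 0.0])
    widths = np.array([np.pi, np.pi / 2, np.pi])  # zyx Euler half-ranges
    best = np.inf
    steps = 14
    for _ in range(8):
        axes = [
            np.linspace(c - w, c + w, steps) for c, w in zip(centers, widths)
        ]
        grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        rot = Rotation.from_euler("zyx", grid).as_matrix()
        vals = rmsd_for(rot)
        k = int(np.argmin(vals))
        if vals[k] < best:
            best = float(vals[k])
            centers = grid[k]
        widths = widths * (2.5 / steps)
    return best
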