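"""Synthetic-data generator: planted-site structures, decoy libraries, holo files.

Every other module is testable offline through this module.  It emulates
the apo/holo asymmetry of real benchmarks: a "site" is a set of residues
with known coordinates; the unperturbed copy becomes the template (the
holo-derived search pattern) while a Gaussian-perturbed copy, surrounded
by decoy residues, becomes the apo-like query.  Geometry is deliberately
unphysical — residues are point pairs placed by rejection sampling, with
side-chain centroids synthesized at a fixed 1.5 Å offset in a random
direction from Cα — because matching operates on pairwise distances only;
what the generator controls is exactly what matters: inter-residue
distances, coordinate noise, decoy density and chain splits.

All randomness flows through numpy's PCG64 generator seeded from the spec,
so the same spec yields byte-identical PDB text on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_model import QueryStructure, ResidueDescriptor, parse_pdb_text
from .template_library import SiteTemplate, TemplateLibrary

#: built-in pool of valid SMILES strings used for generated ligand tables
BUILTIN_SMILES: tuple[str, ...] = (
    "CCO",
    "c1ccccc1",
    "CC(=O)O",
    "C1CCCCC1",
    "CCN(CC)CC",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "c1ccc2c(c1)cccc2",
    "OCC(O)CO",
    "Nc1ncnc2[nH]cnc12",
    "OC(=O)CCC(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "O=C(O)c1ccccc1O",
    "NCCc1ccc(O)c(O)c1",
    "OCC1OC(O)C(O)C(O)C1O",
    "CSCC[C@H](N)C(O)=O",
    "OC(=O)c1cc(O)c(O)c(O)c1",
    "CCCCCCCCCCCCCCCC(=O)O",
    "Nc1ccc(cc1)S(N)(=O)=O",
    "OC(=O)C=Cc1ccccc1",
    "CN1CCC[C@H]1c1cccnc1",
)

#: amino-acid alphabet used for generated residues (glycine excluded so every
#: generated residue carries a distinct side-chain pseudo-atom)
GENERATOR_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

SC_OFFSET = 1.5  # Å, fixed Cα → side-chain-centroid distance
SITE_RADIUS = 8.0  # Å, sphere holding the planted site residues
DECOY_RADIUS = 20.0  # Å, sphere holding decoy residues
MIN_PAIR_DIST = 3.2  # Å, minimum Cα–Cα separation within the site
MIN_DECOY_DIST = 3.0  # Å, minimum decoy separation from every other Cα


class GenerationError(Exception):
    """Packing failed within the retry budget (spec infeasible)."""


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Parameters of one planted-site benchmark structure."""

    n_site_residues: int = 6
    noise_sigma: float = 0.3
    n_decoy_residues: int = 50
    split_across_chains: tuple[int, tuple[int, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_site_residues < 3:
            raise ValueError("a planted site needs at least 3 residues")
        if self.noise_sigma < 0 or self.n_decoy_residues < 0:
            raise ValueError("noise_sigma and n_decoy_residues must be >= 0")
        if self.split_across_chains is not None:
            n_chains, partition = self.split_across_chains
            if n_chains < 2 or len(partition) != n_chains:
                raise ValueError("split needs >= 2 chains and one count per chain")
            if sum(partition) != self.n_site_residues or min(partition) < 1:
                raise ValueError("chain partition must cover all site residues")


# ---------------------------------------------------------------------------
# PDB writing

_ATOM_FMT = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{seq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _atom_line(
    record: str, serial: int, name: str, resname: str, chain: str,
    seq: int, xyz: Sequence[float], element: str = "C", icode: str = "",
    occ: float = 1.0,
) -> str:
    padded = name if len(name) >= 4 else f" {name:<3}"
    return _ATOM_FMT.format(
        record=record, serial=serial, name=padded, altloc="", resname=resname,
        chain=chain, seq=seq, icode=icode or "", x=xyz[0], y=xyz[1], z=xyz[2],
        occ=occ, b=0.0, element=element,
    )


@dataclass(frozen=True)
class HetAtom:
    """One HETATM record for synthetic holo files."""

    resname: str
    chain_id: str
    seq_pos: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


def write_pdb(
    residues: Sequence[ResidueDescriptor],
    het_atoms: Sequence[HetAtom] = (),
) -> str:
    """Emit minimal valid PDB text: one CA (+CB for non-glycine) per residue.

    The CB pseudo-atom carries the side-chain centroid, so re-parsing
    reproduces both representative points to PDB precision (1e-3 Å).
    """
    lines = []
    serial = 1
    for r in residues:
        lines.append(
            _atom_line("ATOM", serial, "CA", r.aa_type, r.chain_id, r.seq_pos,
                       r.ca_coord, icode=r.insertion_code)
        )
        serial += 1
        if r.aa_type != "GLY":
            lines.append(
                _atom_line("ATOM", serial, "CB", r.aa_type, r.chain_id, r.seq_pos,
                           r.sc_centroid, icode=r.insertion_code)
            )
            serial += 1
    for h in het_atoms:
        lines.append(
            _atom_line("HETATM", serial, h.atom_name, h.resname, h.chain_id,
                       h.seq_pos, h.xyz, element=h.element)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# point placement

def _sample_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, 3)
        if float(p @ p) <= radius * radius:
            return p


def _place_points(
    rng: np.random.Generator,
    n: int,
    radius: float,
    min_dist: float,
    existing: Sequence[np.ndarray] = (),
    max_tries: int = 2000,
) -> list[np.ndarray]:
    placed: list[np.ndarray] = []
    anchors = [np.asarray(e) for e in existing]
    for _ in range(n):
        for _ in range(max_tries):
            p = _sample_in_sphere(rng, radius)
            if all(np.linalg.norm(p - q) >= min_dist for q in placed + anchors):
                placed.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {n} points with min distance {min_dist} "
                f"in a sphere of radius {radius}"
            )
    return placed


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = float(np.linalg.norm(v))
        if norm > 1e-8:
            return v / norm


def _residue(
    chain: str, seq: int, aa: str, ca: np.ndarray, sc: np.ndarray
) -> ResidueDescriptor:
    return ResidueDescriptor(
        chain_id=chain, seq_pos=seq, insertion_code="", aa_type=aa,
        ca_coord=tuple(round(float(x), 3) for x in ca),
        sc_centroid=tuple(round(float(x), 3) for x in sc),
    )


# ---------------------------------------------------------------------------
# planted-site generation

def generate_planted_structure(
    spec: PlantedSiteSpec,
    ligand_code: str = "PLS",
    ligand_smiles: str = BUILTIN_SMILES[0],
    template_id: str | None = None,
) -> tuple[str, SiteTemplate]:
    """Generate an apo-like query PDB with a planted site and its ground truth.

    The returned template holds the unperturbed site coordinates (the holo
    frame); the PDB text holds the noise-perturbed copy surrounded by decoy
    residues, optionally split across chains.  Deterministic under
    ``spec.seed``: coordinates are rounded to PDB precision before writing,
    so the template and the re-parsed query agree exactly up to the noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_site_residues

    site_ca = _place_points(rng, n, SITE_RADIUS, MIN_PAIR_DIST)
    aa_types = [GENERATOR_AA[i] for i in rng.integers(0, len(GENERATOR_AA), n)]
    site_sc = [ca + SC_OFFSET * _unit_vector(rng) for ca in site_ca]

    template_residues = [
        _residue("A", i + 1, aa_types[i], site_ca[i], site_sc[i]) for i in range(n)
    ]
    sid = template_id or f"planted-seed{spec.seed}"
    template = SiteTemplate(
        template_id=sid,
        source_structure=f"synthetic-holo-{spec.seed}",
        site_kind="ligand_binding",
        residues=tuple(template_residues),
        ligand_code=ligand_code,
        ligand_smiles=ligand_smiles,
    )

    noisy_ca = [ca + rng.normal(0.0, spec.noise_sigma, 3) for ca in site_ca]
    noisy_sc = [sc + rng.normal(0.0, spec.noise_sigma, 3) for sc in site_sc]

    if spec.split_across_chains is None:
        chain_of_site = ["A"] * n
        chains = ["A"]
    else:
        n_chains, partition = spec.split_across_chains
        chains = [chr(ord("A") + c) for c in range(n_chains)]
        chain_of_site = []
        for c, count in enumerate(partition):
            chain_of_site += [chains[c]] * count

    decoy_ca = _place_points(
        rng, spec.n_decoy_residues, DECOY_RADIUS, MIN_DECOY_DIST, existing=noisy_ca
    )
    decoy_aa = [GENERATOR_AA[i] for i in rng.integers(0, len(GENERATOR_AA),
                                                      spec.n_decoy_residues)]
    decoy_sc = [ca + SC_OFFSET * _unit_vector(rng) for ca in decoy_ca]
    chain_of_decoy = [chains[i % len(chains)] for i in range(spec.n_decoy_residues)]

    next_seq = {c: 1 for c in chains}
    query_residues: list[ResidueDescriptor] = []
    for i in range(n):
        c = chain_of_site[i]
        query_residues.append(_residue(c, next_seq[c], aa_types[i],
                                       noisy_ca[i], noisy_sc[i]))
        next_seq[c] += 1
    for i in range(spec.n_decoy_residues):
        c = chain_of_decoy[i]
        query_residues.append(_residue(c, next_seq[c], decoy_aa[i],
                                       decoy_ca[i], decoy_sc[i]))
        next_seq[c] += 1
    query_residues.sort(key=lambda r: (r.chain_id, r.seq_pos))
    return write_pdb(query_residues), template


def generate_decoy_library(
    n_templates: int,
    sizes: tuple[int, int] = (4, 8),
    seed: int = 0,
    site_kind: str = "ligand_binding",
    id_prefix: str = "decoy",
) -> TemplateLibrary:
    """Random geometric templates with generated ligand codes and SMILES.

    Each template's residues are placed by the same rejection sampler as
    planted sites, so decoys are geometrically plausible but unrelated to
    any query.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    entries = []
    ligand_table: dict[str, str] = {}
    for k in range(n_templates):
        n = int(rng.integers(sizes[0], sizes[1] + 1))
        ca = _place_points(rng, n, SITE_RADIUS, MIN_PAIR_DIST)
        aa = [GENERATOR_AA[i] for i in rng.integers(0, len(GENERATOR_AA), n)]
        sc = [c + SC_OFFSET * _unit_vector(rng) for c in ca]
        residues = tuple(_residue("A", i + 1, aa[i], ca[i], sc[i]) for i in range(n))
        if site_kind == "ligand_binding":
            code = f"D{k:02d}"
            smiles = BUILTIN_SMILES[int(rng.integers(0, len(BUILTIN_SMILES)))]
            ligand_table[code] = smiles
        else:
            code, smiles = "", ""
        entries.append(
            SiteTemplate(
                template_id=f"{id_prefix}-{k:03d}",
                source_structure=f"{id_prefix}-src-{k:03d}",
                site_kind=site_kind,
                residues=residues,
                ligand_code=code,
                ligand_smiles=smiles,
            )
        )
    return TemplateLibrary(
        entries=entries,
        ligand_table=ligand_table,
        metadata={"generator": "decoy", "seed": seed, "sizes": list(sizes)},
    )


@dataclass(frozen=True)
class RecoveryCase:
    """One planted-site recovery trial: query + library with the truth inside."""

    query: QueryStructure
    query_pdb: str
    library: TemplateLibrary
    planted_template_id: str


def generate_recovery_case(
    seed: int,
    n_site_range: tuple[int, int] = (5, 8),
    noise_sigma: float = 0.3,
    n_decoy_residues: int = 50,
    n_decoy_templates: int = 50,
    split_across_chains: tuple[int, tuple[int, ...]] | None = None,
) -> RecoveryCase:
    """A full benchmark trial: planted query vs (planted + decoy) library."""
    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, 3)]
    n_site = int(rng.integers(n_site_range[0], n_site_range[1] + 1))
    if split_across_chains is not None:
        n_site = sum(split_across_chains[1])

    spec = PlantedSiteSpec(
        n_site_residues=n_site,
        noise_sigma=noise_sigma,
        n_decoy_residues=n_decoy_residues,
        split_across_chains=split_across_chains,
        seed=sub_seeds[0],
    )
    planted_smiles = BUILTIN_SMILES[sub_seeds[1] % len(BUILTIN_SMILES)]
    pdb_text, template = generate_planted_structure(
        spec, ligand_code="PL1", ligand_smiles=planted_smiles,
        template_id=f"planted-{seed}",
    )
    library = generate_decoy_library(n_decoy_templates, seed=sub_seeds[2])
    library.entries.append(template)
    library.ligand_table[template.ligand_code] = template.ligand_smiles
    library.metadata["recovery_seed"] = seed
    query = parse_pdb_text(pdb_text, structure_id=f"planted-query-{seed}")
    return RecoveryCase(
        query=query,
        query_pdb=pdb_text,
        library=library,
        planted_template_id=template.template_id,
    )


# ---------------------------------------------------------------------------
# synthetic holo structures (for template extraction / build-db paths)

def generate_holo_structure(
    seed: int = 0,
    n_contact: int = 6,
    n_far: int = 5,
    ligand_code: str = "LIG",
    n_ligand_atoms: int = 3,
    contact_radius: float = 3.5,
    far_radius: float = 14.0,
    duplicate_instance: bool = False,
) -> str:
    """A synthetic holo PDB: a fake ligand with near and far residue shells.

    ``n_contact`` residues have their Cα at ``contact_radius`` Å from the
    ligand center, ``n_far`` residues sit at ``far_radius`` Å, so a contact
    cutoff between the two radii extracts exactly the near shell.  With
    ``duplicate_instance`` a second, translated copy of ligand + near shell
    is added on chain B.
    """
    rng = np.random.default_rng(seed)

    def shell(center: np.ndarray, chain: str, n: int, radius: float,
              seq_start: int) -> list[ResidueDescriptor]:
        out = []
        for i in range(n):
            direction = _unit_vector(rng)
            ca = center + radius * direction
            sc = ca + SC_OFFSET * direction  # side chain points away from ligand
            aa = GENERATOR_AA[int(rng.integers(0, len(GENERATOR_AA)))]
            out.append(_residue(chain, seq_start + i, aa, ca, sc))
        return out

    center_a = np.zeros(3)
    residues = shell(center_a, "A", n_contact, contact_radius, 1)
    residues += shell(center_a, "A", n_far, far_radius, n_contact + 1)
    hets = [
        HetAtom(ligand_code, "A", 900, f"C{i + 1}", "C",
                tuple(round(float(x), 3)
                      for x in center_a + 0.5 * i * np.array([1.0, 0.0, 0.0])))
        for i in range(n_ligand_atoms)
    ]
    if duplicate_instance:
        center_b = np.array([60.0, 0.0, 0.0])
        residues += shell(center_b, "B", n_contact, contact_radius, 1)
        hets += [
            HetAtom(ligand_code, "B", 900, f"C{i + 1}", "C",
                    tuple(round(float(x), 3)
                          for x in center_b + 0.5 * i * np.array([1.0, 0.0, 0.0])))
            for i in range(n_ligand_atoms)
        ]
    return write_pdb(residues, het_atoms=hets)
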