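"""Residue-level representation of protein structures.

Each residue is reduced to two pseudo-atoms: the Cα position and the centroid
of the side-chain heavy atoms (for glycine, which has no side chain, the
centroid degenerates to Cα).  All downstream matching operates on these
pseudo-atoms only, so side-chain orientation contributes to the geometry
without requiring full-atom correspondence.

Parsing is backed by gemmi and accepts both PDB and mmCIF files.  Only
standard amino-acid residues possessing a Cα atom are retained; HETATM
ligands, waters and nucleic acids are excluded, selenomethionine (MSE) is
mapped to MET, and any other non-standard residue is dropped with a warning.
Alternate locations are resolved per atom name to the highest-occupancy
conformer (ties broken by file order).  Author numbering is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset(
    [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    ]
)

#: residue-name substitutions applied at parse time (modified residues that
#: are chemically close enough to a standard parent for matching purposes)
AA_SUBSTITUTIONS: Mapping[str, str] = {"MSE": "MET"}

_WATER_NAMES = frozenset(["HOH", "WAT", "DOD", "H2O"])
_BACKBONE_ATOMS = frozenset(["N", "CA", "C", "O", "OXT"])


class StructureError(Exception):
    """Base class for structure-handling errors."""


class ParseError(StructureError):
    """The file could not be read or parsed."""


class EmptyStructureError(StructureError):
    """No standard amino-acid residue survived parsing/filtering."""


class LigandNotFoundError(StructureError):
    """The requested HET code is absent from the structure."""


@dataclass(frozen=True)
class ResidueDescriptor:
    """One residue: identity plus its two representative coordinates (Å)."""

    chain_id: str
    seq_pos: int
    insertion_code: str
    aa_type: str
    ca_coord: tuple[float, float, float]
    sc_centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.aa_type not in STANDARD_AA:
            raise ValueError(f"non-standard aa_type {self.aa_type!r}")
        for v in (*self.ca_coord, *self.sc_centroid):
            if not math.isfinite(v):
                raise ValueError("residue coordinates must be finite")

    @property
    def ca(self) -> np.ndarray:
        return np.asarray(self.ca_coord, dtype=float)

    @property
    def sc(self) -> np.ndarray:
        return np.asarray(self.sc_centroid, dtype=float)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.insertion_code)

    @property
    def label(self) -> str:
        ic = self.insertion_code
        return f"{self.chain_id}:{self.seq_pos}{ic}:{self.aa_type}"


@dataclass(frozen=True)
class QueryStructure:
    """Uniform residue-level view of a parsed structure."""

    structure_id: str
    residues: tuple[ResidueDescriptor, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, seq_pos, insertion_code) keys")

    @property
    def chain_ids(self) -> frozenset[str]:
        return frozenset(r.chain_id for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def subset(self, chains: Iterable[str]) -> tuple["QueryStructure", list[int]]:
        """Restrict to the given chains.

        Returns the restricted structure and the list mapping each restricted
        residue index back to its index in ``self.residues``.
        """
        chains = set(chains)
        idx = [i for i, r in enumerate(self.residues) if r.chain_id in chains]
        sub = QueryStructure(
            structure_id=self.structure_id,
            residues=tuple(self.residues[i] for i in idx),
        )
        return sub, idx

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    def sc_array(self) -> np.ndarray:
        return np.array([r.sc_centroid for r in self.residues], dtype=float)


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Pick one atom per atom name: highest occupancy, ties → first in file."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return list(chosen.values())


def _heavy(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    return [a for a in atoms if not a.is_hydrogen()]


def _descriptor_from_residue(chain_id: str, residue: gemmi.Residue) -> ResidueDescriptor | None:
    aa = AA_SUBSTITUTIONS.get(residue.name, residue.name)
    atoms = _heavy(_select_altlocs(residue))
    ca = next((a for a in atoms if a.name == "CA"), None)
    if ca is None:
        return None
    side = [a for a in atoms if a.name not in _BACKBONE_ATOMS and a.name != "SE"]
    # MSE selenium maps onto MET SD for centroid purposes
    side += [a for a in atoms if a.name == "SE"]
    if side:
        pos = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in side]).mean(axis=0)
        sc = (float(pos[0]), float(pos[1]), float(pos[2]))
    else:
        sc = (ca.pos.x, ca.pos.y, ca.pos.z)
    icode = residue.seqid.icode.strip()
    return ResidueDescriptor(
        chain_id=chain_id,
        seq_pos=residue.seqid.num,
        insertion_code=icode,
        aa_type=aa,
        ca_coord=(ca.pos.x, ca.pos.y, ca.pos.z),
        sc_centroid=sc,
    )


def _read_structure(path: str | Path) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with file context
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no model found in {path}")
    return st


def _structure_from_text(text: str, structure_id: str) -> gemmi.Structure:
    try:
        st = gemmi.read_pdb_string(text)
    except Exception as exc:
        raise ParseError(f"cannot parse PDB text for {structure_id}: {exc}") from exc
    st.name = structure_id
    return st


def _collect_residues(
    model: gemmi.Model, chains: Iterable[str] | None
) -> list[ResidueDescriptor]:
    chain_filter = set(chains) if chains is not None else None
    out: list[ResidueDescriptor] = []
    seen: set[tuple[str, int, str]] = set()
    dropped: set[str] = set()
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for residue in chain:
            name = AA_SUBSTITUTIONS.get(residue.name, residue.name)
            if name not in STANDARD_AA:
                if residue.name not in _WATER_NAMES:
                    dropped.add(residue.name)
                continue
            desc = _descriptor_from_residue(chain.name, residue)
            if desc is None:
                logger.warning(
                    "residue %s %s%d has no CA atom; dropped",
                    residue.name, chain.name, residue.seqid.num,
                )
                continue
            if desc.key in seen:
                logger.warning("duplicate residue %s; keeping first occurrence", desc.key)
                continue
            seen.add(desc.key)
            out.append(desc)
    if dropped:
        logger.warning("dropped non-standard residues: %s", ", ".join(sorted(dropped)))
    return out


def parse_structure(
    path: str | Path,
    model_index: int = 0,
    chains: Iterable[str] | None = None,
) -> QueryStructure:
    """Parse a PDB/mmCIF file into a :class:`QueryStructure`.

    Parameters
    ----------
    path:
        Structure file (PDB or mmCIF; format autodetected).
    model_index:
        Which model of a multi-model file to use (default: first).
    chains:
        Optional chain filter; residues outside these chains are ignored.

    Raises
    ------
    ParseError
        If the file cannot be read or the model index is out of range.
    EmptyStructureError
        If no standard amino-acid residue with a Cα atom survives filtering.
    """
    st = _read_structure(path)
    return _query_from_gemmi(st, model_index, chains, source=str(path))


def parse_pdb_text(
    text: str,
    structure_id: str = "in-memory",
    model_index: int = 0,
    chains: Iterable[str] | None = None,
) -> QueryStructure:
    """Parse PDB-format text directly (used by the synthetic-data generator)."""
    st = _structure_from_text(text, structure_id)
    return _query_from_gemmi(st, model_index, chains, source=structure_id)


def _query_from_gemmi(
    st: gemmi.Structure,
    model_index: int,
    chains: Iterable[str] | None,
    source: str,
) -> QueryStructure:
    if model_index < 0 or model_index >= len(st):
        raise ParseError(
            f"model index {model_index} out of range for {source} ({len(st)} model(s))"
        )
    residues = _collect_residues(st[model_index], chains)
    if not residues:
        raise EmptyStructureError(
            f"no standard amino-acid residues selected from {source}"
            + (f" with chain filter {sorted(set(chains))}" if chains else "")
        )
    sid = Path(source).stem if source else st.name
    return QueryStructure(structure_id=sid or "structure", residues=tuple(residues))


def list_ligand_instances(
    path: str | Path, model_index: int = 0
) -> list[tuple[str, str, int]]:
    """List HET groups in a file as ``(het_code, chain_id, seq_pos)`` tuples.

    Waters are excluded; standard residues are never listed.
    """
    st = _read_structure(path)
    if model_index >= len(st):
        raise ParseError(f"model index {model_index} out of range for {path}")
    out = []
    for chain in st[model_index]:
        for residue in chain:
            if residue.name in STANDARD_AA or residue.name in AA_SUBSTITUTIONS:
                continue
            if residue.name in _WATER_NAMES:
                continue
            out.append((residue.name, chain.name, residue.seqid.num))
    out.sort(key=lambda t: (t[1], t[2], t[0]))
    return out


def extract_ligand_contacts(
    holo_path: str | Path,
    ligand_code: str,
    contact_cutoff: float = 4.5,
    instance: int | tuple[str, int] | None = None,
    model_index: int = 0,
) -> tuple[list[ResidueDescriptor], str]:
    """Residues in contact with a bound ligand in a holo structure.

    A residue is a contact if any of its heavy atoms lies within
    ``contact_cutoff`` Å of any heavy atom of the selected ligand instance.
    Instances of ``ligand_code`` are ordered by (chain, seq_pos); ``instance``
    selects one by index or by ``(chain_id, seq_pos)``; default is the first.

    Returns the contact residues ordered by (chain, seq_pos, insertion code)
    and the instance id ``"CHAIN:SEQ"``.
    """
    st = _read_structure(holo_path)
    if model_index >= len(st):
        raise ParseError(f"model index {model_index} out of range for {holo_path}")
    model = st[model_index]

    instances: list[tuple[str, int, gemmi.Residue]] = []
    present: set[str] = set()
    for chain in model:
        for residue in chain:
            if residue.name in STANDARD_AA or residue.name in AA_SUBSTITUTIONS:
                continue
            if residue.name in _WATER_NAMES:
                continue
            present.add(residue.name)
            if residue.name == ligand_code:
                instances.append((chain.name, residue.seqid.num, residue))
    if not instances:
        raise LigandNotFoundError(
            f"ligand {ligand_code!r} not found in {holo_path}; "
            f"HET codes present: {sorted(present) or 'none'}"
        )
    instances.sort(key=lambda t: (t[0], t[1]))

    if instance is None:
        sel = instances[0]
    elif isinstance(instance, int):
        if instance < 0 or instance >= len(instances):
            raise LigandNotFoundError(
                f"ligand instance index {instance} out of range "
                f"({len(instances)} instance(s) of {ligand_code!r})"
            )
        sel = instances[instance]
    else:
        chain_id, seq = instance
        match = [t for t in instances if t[0] == chain_id and t[1] == seq]
        if not match:
            raise LigandNotFoundError(
                f"no instance of {ligand_code!r} at {chain_id}:{seq}; "
                f"instances: {[(c, s) for c, s, _ in instances]}"
            )
        sel = match[0]

    lig_atoms = _heavy(_select_altlocs(sel[2]))
    lig_xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in lig_atoms])

    contacts: list[ResidueDescriptor] = []
    for chain in model:
        for residue in chain:
            name = AA_SUBSTITUTIONS.get(residue.name, residue.name)
            if name not in STANDARD_AA:
                continue
            atoms = _heavy(_select_altlocs(residue))
            if not atoms:
                continue
            xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            d2 = ((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= contact_cutoff**2:
                desc = _descriptor_from_residue(chain.name, residue)
                if desc is not None:
                    contacts.append(desc)
    contacts.sort(key=lambda r: r.key)
    return contacts, f"{sel[0]}:{sel[1]}"
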