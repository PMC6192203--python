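"""SMILES-based ligand fingerprinting and similarity clustering.

Ligands are fingerprinted from their SMILES strings and grouped with the
Taylor–Butina leader algorithm at a Tanimoto threshold.  Each ligand's
cluster then yields a relative-size weight in (0, 1] — by default the
cluster size divided by the size of the largest cluster — which the scorer
uses as the chemical-context term: a hit whose template ligand belongs to a
large family of similar ligands carries more weight than one from a
chemical singleton.

Fingerprints are Morgan (circular, radius 2, 2048 bits) when rdkit is
importable; otherwise a hashed character-3-gram fingerprint over the raw
SMILES string is used.  The 3-gram fallback does not canonicalize SMILES,
so two different writings of the same molecule may fingerprint differently;
the backend in use is recorded in output metadata.
"""

from __future__ import annotations

import csv
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

try:  # optional cheminformatics backend
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    _HAVE_RDKIT = True
except ImportError:  # pragma: no cover - exercised only without rdkit
    _HAVE_RDKIT = False

N_BITS = 2048
DEFAULT_SIM_THRESHOLD = 0.7
BACKENDS = ("auto", "rdkit", "kgram")
CLUSTER_NORMS = ("largest", "total")


def resolve_backend(backend: str = "auto") -> str:
    """Resolve ``auto`` to the backend actually available."""
    if backend not in BACKENDS:
        raise ValueError(f"unknown fingerprint backend {backend!r}")
    if backend == "auto":
        return "rdkit" if _HAVE_RDKIT else "kgram"
    if backend == "rdkit" and not _HAVE_RDKIT:
        raise RuntimeError("rdkit backend requested but rdkit is not importable")
    return backend


def _kgram_fingerprint(smiles: str, n_bits: int) -> np.ndarray:
    """Hashed character-3-gram fingerprint (rdkit-free fallback)."""
    bits = np.zeros(n_bits, dtype=bool)
    s = smiles if len(smiles) >= 3 else smiles + "_" * (3 - len(smiles))
    for i in range(len(s) - 2):
        gram = s[i : i + 3].encode("utf-8")
        idx = int.from_bytes(hashlib.blake2b(gram, digest_size=4).digest(), "big")
        bits[idx % n_bits] = True
    return bits


def _rdkit_fingerprint(smiles: str, n_bits: int) -> np.ndarray | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(bool)


def fingerprint(
    smiles: str, n_bits: int = N_BITS, backend: str = "auto"
) -> np.ndarray | None:
    """Bit-vector fingerprint of a SMILES string, or None if unparseable.

    With the rdkit backend the SMILES is parsed (and thereby canonicalized)
    before hashing; an unparseable or empty SMILES yields None — a flagged
    invalid, never an exception.  The fallback backend flags only empty
    SMILES as invalid.
    """
    if not smiles:
        return None
    if resolve_backend(backend) == "rdkit":
        return _rdkit_fingerprint(smiles, n_bits)
    return _kgram_fingerprint(smiles, n_bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit vectors.

    Defined as 1.0 when both vectors are all-zero (identical, if empty).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


@dataclass
class LigandRecord:
    """One ligand: HET code, SMILES, and its fingerprint (None if invalid)."""

    ligand_code: str
    smiles: str
    fingerprint: np.ndarray | None = None

    @property
    def valid(self) -> bool:
        return self.fingerprint is not None


@dataclass(frozen=True)
class LigandCluster:
    """A Butina cluster with its relative-size weight."""

    cluster_id: int
    members: frozenset[str]
    rel_size: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        if not 0.0 < self.rel_size <= 1.0:
            raise ValueError(f"rel_size {self.rel_size} outside (0, 1]")

    @property
    def size(self) -> int:
        return len(self.members)


def make_records(
    ligand_table: Mapping[str, str], backend: str = "auto"
) -> list[LigandRecord]:
    """Fingerprint every entry of a ligand_code → SMILES table (sorted by code)."""
    records = []
    for code in sorted(ligand_table):
        smiles = ligand_table[code]
        records.append(
            LigandRecord(code, smiles, fingerprint=fingerprint(smiles, backend=backend))
        )
    invalid = [r.ligand_code for r in records if not r.valid]
    if invalid:
        logger.warning("unparseable SMILES for: %s", ", ".join(invalid))
    return records


def cluster_ligands(
    records: Sequence[LigandRecord],
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    norm: str = "largest",
) -> list[LigandCluster]:
    """Taylor–Butina leader clustering at Tanimoto ≥ ``sim_threshold``.

    Ligands are sorted by neighbour count (descending; ties by ligand code);
    the densest unassigned ligand repeatedly becomes a cluster centroid
    together with its unassigned neighbours.  Singletons are allowed.
    Invalid records (no fingerprint) are excluded from clustering.

    ``norm`` controls rel_size: ``"largest"`` divides by the largest
    cluster's size (max weight exactly 1), ``"total"`` by the number of
    clustered ligands.
    """
    if norm not in CLUSTER_NORMS:
        raise ValueError(f"unknown cluster norm {norm!r}")
    usable = sorted((r for r in records if r.valid), key=lambda r: r.ligand_code)
    if not usable:
        return []
    n = len(usable)
    fps = np.array([r.fingerprint for r in usable], dtype=bool)
    inter = (fps[:, None, :] & fps[None, :, :]).sum(axis=2).astype(float)
    union = (fps[:, None, :] | fps[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    neighbors = [set(np.flatnonzero(sim[i] >= sim_threshold)) - {i} for i in range(n)]

    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), usable[i].ligand_code))
    assigned: set[int] = set()
    raw_clusters: list[list[int]] = []
    for centroid in order:
        if centroid in assigned:
            continue
        members = [centroid] + sorted(m for m in neighbors[centroid] if m not in assigned)
        assigned.update(members)
        raw_clusters.append(members)

    max_size = max(len(m) for m in raw_clusters)
    denom = max_size if norm == "largest" else n
    return [
        LigandCluster(
            cluster_id=cid,
            members=frozenset(usable[i].ligand_code for i in members),
            rel_size=len(members) / denom,
        )
        for cid, members in enumerate(raw_clusters)
    ]


@dataclass(frozen=True)
class ClusterTable:
    """Ligand → relative-cluster-size lookup with a fallback for unknowns.

    A ligand code missing from the table (e.g. added after clustering) falls
    back to the weight of a hypothetical singleton, 1 / largest-cluster-size.
    """

    rel_size_by_code: Mapping[str, float]
    cluster_by_code: Mapping[str, int]
    size_by_code: Mapping[str, int]
    largest_size: int
    backend: str
    sim_threshold: float
    norm: str = "largest"

    def rel_size(self, ligand_code: str) -> float:
        try:
            return self.rel_size_by_code[ligand_code]
        except KeyError:
            logger.warning(
                "ligand %s not in cluster table; using singleton fallback", ligand_code
            )
            return 1.0 / max(self.largest_size, 1)

    @classmethod
    def from_clusters(
        cls,
        clusters: Sequence[LigandCluster],
        backend: str,
        sim_threshold: float,
        norm: str = "largest",
    ) -> "ClusterTable":
        rel, cid, size = {}, {}, {}
        for c in clusters:
            for code in c.members:
                rel[code] = c.rel_size
                cid[code] = c.cluster_id
                size[code] = c.size
        largest = max((c.size for c in clusters), default=1)
        return cls(rel, cid, size, largest, backend, sim_threshold, norm)


def build_cluster_table(
    ligand_table: Mapping[str, str],
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    backend: str = "auto",
    norm: str = "largest",
) -> ClusterTable:
    """Fingerprint, cluster and index a ligand table in one step."""
    backend = resolve_backend(backend)
    records = make_records(ligand_table, backend=backend)
    clusters = cluster_ligands(records, sim_threshold=sim_threshold, norm=norm)
    return ClusterTable.from_clusters(clusters, backend, sim_threshold, norm)


def write_cluster_table(table: ClusterTable, path: str | Path) -> None:
    """Write ``ligand_code,cluster_id,cluster_size,rel_size`` CSV."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["ligand_code", "cluster_id", "cluster_size", "rel_size"])
    for code in sorted(table.rel_size_by_code):
        writer.writerow(
            [
                code,
                table.cluster_by_code[code],
                table.size_by_code[code],
                f"{table.rel_size_by_code[code]:.6f}",
            ]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cluster_table(
    path: str | Path, backend: str = "unknown", sim_threshold: float = float("nan")
) -> ClusterTable:
    rel, cid, size = {}, {}, {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            code = row["ligand_code"]
            rel[code] = float(row["rel_size"])
            cid[code] = int(row["cluster_id"])
            size[code] = int(row["cluster_size"])
    largest = max(size.values(), default=1)
    return ClusterTable(rel, cid, size, largest, backend, sim_threshold)
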