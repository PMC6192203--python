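"""Site-template library: build, serialize and load binding/catalytic sites.

On-disk format: versioned JSON-lines (UTF-8).  The first line is a header
record ``{"format": "pocketclique-lib", "version": 1, "metadata": {...},
"ligand_table": {...}}``; every subsequent non-empty line is one template.
JSON-lines keeps libraries diffable and streamable, and floats round-trip
exactly through Python's JSON encoder.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .structure_model import ResidueDescriptor, extract_ligand_contacts

logger = logging.getLogger(__name__)

FORMAT_NAME = "pocketclique-lib"
FORMAT_VERSION = 1

SITE_KINDS = ("ligand_binding", "catalytic")

#: HET codes excluded by default when building templates: waters, common
#: ions, and frequent crystallization additives.  Configurable at build time.
DEFAULT_EXCLUDED_LIGANDS = frozenset(
    [
        "HOH", "WAT", "DOD", "H2O",
        "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "NI",
        "CO", "CD", "HG", "BR", "IOD", "CS", "SR", "BA", "LI",
        "SO4", "PO4", "NO3", "ACT", "FMT", "CO3",
        "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "BME", "TRS",
        "EPE", "MES", "IMD", "ACE", "NH4",
    ]
)


class LibraryError(Exception):
    """Base class for template-library errors."""


class TooSmallSiteError(LibraryError):
    """A site with fewer than 3 residues cannot constrain a rigid match."""


class UnsupportedVersionError(LibraryError):
    """The library file declares a format version this reader does not know."""


class LibraryFormatError(LibraryError):
    """Malformed library file (reported with the offending line number)."""


MIN_SITE_RESIDUES = 3


@dataclass(frozen=True)
class SiteTemplate:
    """A known binding or catalytic site used as a search pattern.

    ``residues`` hold the template-frame coordinates; ``ligand_code`` is the
    3-letter HET code of the bound ligand (empty for catalytic sites).
    """

    template_id: str
    source_structure: str
    site_kind: str
    residues: tuple[ResidueDescriptor, ...]
    ligand_code: str = ""
    ligand_smiles: str = ""

    def __post_init__(self) -> None:
        if self.site_kind not in SITE_KINDS:
            raise ValueError(f"unknown site_kind {self.site_kind!r}")
        if len(self.residues) < MIN_SITE_RESIDUES:
            raise TooSmallSiteError(
                f"template {self.template_id!r} has {len(self.residues)} residues; "
                f"at least {MIN_SITE_RESIDUES} are required"
            )
        if self.site_kind == "ligand_binding" and not self.ligand_code:
            raise ValueError(
                f"ligand_binding template {self.template_id!r} lacks a ligand_code"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TemplateLibrary:
    """A collection of site templates plus the ligand → SMILES table."""

    entries: list[SiteTemplate] = field(default_factory=list)
    ligand_table: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.template_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate template_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def missing_smiles(self) -> frozenset[str]:
        """Ligand codes referenced by entries but absent from the table."""
        return frozenset(
            e.ligand_code
            for e in self.entries
            if e.ligand_code and e.ligand_code not in self.ligand_table
        )


def build_template(
    holo_path: str | Path,
    ligand_code: str,
    contact_cutoff: float = 4.5,
    instance: int | tuple[str, int] | None = None,
    site_kind: str = "ligand_binding",
    ligand_smiles: str = "",
    template_id: str | None = None,
) -> SiteTemplate:
    """Extract the residues around one bound ligand into a :class:`SiteTemplate`.

    Raises :class:`TooSmallSiteError` when fewer than 3 residues lie within
    ``contact_cutoff`` Å of the ligand, so degenerate sites never enter a
    library.
    """
    residues, instance_id = extract_ligand_contacts(
        holo_path, ligand_code, contact_cutoff=contact_cutoff, instance=instance
    )
    source = Path(holo_path).stem
    if len(residues) < MIN_SITE_RESIDUES:
        raise TooSmallSiteError(
            f"only {len(residues)} residue(s) within {contact_cutoff} Å of "
            f"{ligand_code} {instance_id} in {source}; need {MIN_SITE_RESIDUES}"
        )
    return SiteTemplate(
        template_id=template_id or f"{source}:{ligand_code}:{instance_id}",
        source_structure=source,
        site_kind=site_kind,
        residues=tuple(residues),
        ligand_code=ligand_code,
        ligand_smiles=ligand_smiles,
    )


def _residue_to_json(r: ResidueDescriptor) -> dict:
    return {
        "chain": r.chain_id,
        "seq": r.seq_pos,
        "icode": r.insertion_code,
        "aa": r.aa_type,
        "ca": list(r.ca_coord),
        "sc": list(r.sc_centroid),
    }


def _residue_from_json(d: Mapping) -> ResidueDescriptor:
    return ResidueDescriptor(
        chain_id=d["chain"],
        seq_pos=int(d["seq"]),
        insertion_code=d["icode"],
        aa_type=d["aa"],
        ca_coord=tuple(float(x) for x in d["ca"]),
        sc_centroid=tuple(float(x) for x in d["sc"]),
    )


def _template_to_json(t: SiteTemplate) -> dict:
    return {
        "template_id": t.template_id,
        "source_structure": t.source_structure,
        "site_kind": t.site_kind,
        "ligand_code": t.ligand_code,
        "ligand_smiles": t.ligand_smiles,
        "residues": [_residue_to_json(r) for r in t.residues],
    }


def _template_from_json(d: Mapping) -> SiteTemplate:
    return SiteTemplate(
        template_id=d["template_id"],
        source_structure=d["source_structure"],
        site_kind=d["site_kind"],
        residues=tuple(_residue_from_json(r) for r in d["residues"]),
        ligand_code=d.get("ligand_code", ""),
        ligand_smiles=d.get("ligand_smiles", ""),
    )


def dumps_library(lib: TemplateLibrary) -> str:
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "metadata": lib.metadata,
        "ligand_table": dict(sorted(lib.ligand_table.items())),
    }
    lines = [json.dumps(header, sort_keys=True)]
    lines += [json.dumps(_template_to_json(t), sort_keys=True) for t in lib.entries]
    return "\n".join(lines) + "\n"


def save_library(lib: TemplateLibrary, path: str | Path) -> None:
    Path(path).write_text(dumps_library(lib), encoding="utf-8")


def loads_library(text: str, source: str = "<string>") -> TemplateLibrary:
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise LibraryFormatError(f"{source}: empty library file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise LibraryFormatError(f"{source}, line 1: malformed header: {exc}") from exc
    if not isinstance(header, dict) or header.get("format") != FORMAT_NAME:
        raise LibraryFormatError(
            f"{source}, line 1: not a {FORMAT_NAME} file (header {header!r:.80})"
        )
    version = header.get("version")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"{source}: library format version {version!r} is not supported "
            f"(this reader handles version {FORMAT_VERSION})"
        )
    entries: list[SiteTemplate] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            entries.append(_template_from_json(json.loads(line)))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise LibraryFormatError(f"{source}, line {lineno}: {exc}") from exc
    lib = TemplateLibrary(
        entries=entries,
        ligand_table=dict(header.get("ligand_table", {})),
        metadata=dict(header.get("metadata", {})),
    )
    if lib.missing_smiles:
        logger.warning(
            "%s: no SMILES for ligand code(s): %s",
            source, ", ".join(sorted(lib.missing_smiles)),
        )
    return lib


def load_library(path: str | Path) -> TemplateLibrary:
    return loads_library(Path(path).read_text(encoding="utf-8"), source=str(path))


def read_ligand_table(path: str | Path) -> dict[str, str]:
    """Read a ``ligand_code,smiles`` CSV (header row required)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "ligand_code" not in reader.fieldnames:
            raise LibraryError(f"{path}: expected CSV header 'ligand_code,smiles'")
        return {row["ligand_code"]: row.get("smiles", "") or "" for row in reader}


def write_ligand_table(table: Mapping[str, str], path: str | Path) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["ligand_code", "smiles"])
    for code in sorted(table):
        writer.writerow([code, table[code]])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
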