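"""Run configuration: every tunable of the pipeline in one place.

A :class:`RunConfig` round-trips through TOML or JSON files, command-line
flags override file values, and a short hash of the effective configuration
is embedded in every output's metadata block so results are traceable to
the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

from .clique_matcher import AA_MODES, MatchParams
from .ligand_clustering import BACKENDS, CLUSTER_NORMS
from .scoring import ScoreWeights


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their documented defaults.

    Geometry: ``dist_tol`` (Å) bounds pairwise-distance disagreement in the
    association graph; ``min_clique_size`` the smallest reported
    correspondence; ``rmsd_cutoff`` (Å) discards poor superpositions;
    ``contact_cutoff`` (Å) defines template contact residues.  Chemistry:
    ``sim_threshold`` is the Butina Tanimoto threshold,
    ``fingerprint_backend`` selects rdkit/k-gram, ``cluster_norm`` the
    rel_size normalization.  Scoring: ``w_clique``, ``w_rmsd``,
    ``w_ligand``, ``rmsd_scale`` parameterize the composite score.
    """

    dist_tol: float = 1.5
    min_clique_size: int = 3
    rmsd_cutoff: float = 3.0
    interface_mode: bool = False
    aa_mode: str = "strict"
    contact_cutoff: float = 4.5
    sim_threshold: float = 0.7
    fingerprint_backend: str = "auto"
    cluster_norm: str = "largest"
    w_clique: float = 1.0
    w_rmsd: float = 1.0
    w_ligand: float = 0.5
    rmsd_scale: float = 1.5
    edge_budget: int = 200_000
    max_cliques: int = 100
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aa_mode not in AA_MODES:
            raise ConfigError(f"aa_mode must be one of {AA_MODES}")
        if self.fingerprint_backend not in BACKENDS:
            raise ConfigError(f"fingerprint_backend must be one of {BACKENDS}")
        if self.cluster_norm not in CLUSTER_NORMS:
            raise ConfigError(f"cluster_norm must be one of {CLUSTER_NORMS}")
        if self.min_clique_size < 3:
            raise ConfigError("min_clique_size must be >= 3")
        if not 0.0 < self.sim_threshold <= 1.0:
            raise ConfigError("sim_threshold must be in (0, 1]")
        for name in ("dist_tol", "rmsd_cutoff", "contact_cutoff", "rmsd_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.top_k < 1 or self.edge_budget < 1 or self.max_cliques < 1:
            raise ConfigError("top_k, edge_budget and max_cliques must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @property
    def match_params(self) -> MatchParams:
        return MatchParams(
            dist_tol=self.dist_tol,
            min_clique_size=self.min_clique_size,
            rmsd_cutoff=self.rmsd_cutoff,
            aa_mode=self.aa_mode,
            interface_mode=self.interface_mode,
            edge_budget=self.edge_budget,
            max_cliques=self.max_cliques,
        )

    @property
    def score_weights(self) -> ScoreWeights:
        return ScoreWeights(
            w_clique=self.w_clique,
            w_rmsd=self.w_rmsd,
            w_ligand=self.w_ligand,
            rmsd_scale=self.rmsd_scale,
        )

    def override(self, **kwargs: Any) -> "RunConfig":
        """New config with non-None overrides applied."""
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {unknown}")
        return cls(**dict(data))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from TOML (``.toml``) or JSON (anything else)."""
        path = Path(path)
        try:
            if path.suffix.lower() == ".toml":
                data = tomllib.loads(path.read_text(encoding="utf-8"))
            else:
                data = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, ValueError) as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a table/object")
        return cls.from_mapping(data)
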