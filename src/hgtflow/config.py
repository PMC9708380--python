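"""Run configuration: every numeric threshold of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    alpha_contig: float = 1e-4  # phase-1 (contiguous) merge significance
    alpha_global: float = 1e-8  # phase-2 (global) merge significance
    alpha_net: float = 1e-8  # cross-genome similarity significance
    e_max: float = 0.01  # marker hit E-value cutoff (inclusive)
    fold_cutoff: float = 1.25  # minimum fold enrichment vs native
    enrich_alpha: float = 0.05  # hypergeometric significance
    app_aberrant_max: float = 0.30  # presence fraction at/below which gene is aberrant
    app_escalate_min: float = 0.80  # presence fraction above which cascade escalates
    qcov_min: float = 0.70
    pident_species: float = 60.0
    pident_genus: float = 50.0
    pident_family: float = 25.0
    bootstrap_count: int = 2500
    alphabet_id: str = "sense61"
    exclude_conspecific: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_contig", "alpha_global", "alpha_net", "enrich_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("app_aberrant_max", "app_escalate_min", "qcov_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def digest(self) -> str:
        """Short stable hash of the configuration, echoed in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:10]

    @property
    def pident_cutoffs(self) -> dict[str, float]:
        return {
            "species": self.pident_species,
            "genus": self.pident_genus,
            "family": self.pident_family,
        }
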