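"""Pipeline configuration: one YAML file, strict keys, hashed for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for an end-to-end run.

    Threshold defaults encode the screening cutoffs of the analysis:
    |log2FC| > 1 with adjusted p < 0.05 for the DE stage, rho > 0.4 with
    p < 0.001 for the ligand screen, rho > 0.5 with p < 0.001 for the
    lncRNA-mRNA pair rule, nominal p < 0.05 for the negative miRNA
    co-expression rule, and univariate Cox entry at p < 0.05.
    """

    expression: str = ""
    clinical: str = ""
    fractions: str = ""
    lnc_mi: list = field(default_factory=list)    # one or more TSV paths
    mi_mrna: list = field(default_factory=list)
    gmt: str = ""
    ct: str = ""
    ligands: list = field(default_factory=list)   # two ligand mRNA ids
    outdir: str = "results"
    seed: int = 0

    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    rho_min: float = 0.4
    p_max: float = 0.001
    rho_pos_min: float = 0.5
    neg_p_max: float = 0.05
    univ_p_enter: float = 0.05
    n_perm: int = 1000
    weight: float = 1.0
    pseudocount: float = 1.0

    tumor_only: bool = True
    triplet_candidates: str = "de"      # "de" or "intersected"
    triplet_targets: str = "all"        # "all" or "ligands"
    skip_stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        probs = {"p_threshold": self.p_threshold, "p_max": self.p_max,
                 "neg_p_max": self.neg_p_max, "univ_p_enter": self.univ_p_enter}
        for name, value in probs.items():
            if not (0.0 < value <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1], got {value}")
        for name, value in (("rho_min", self.rho_min),
                            ("rho_pos_min", self.rho_pos_min)):
            if not (-1.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [-1, 1], got {value}")
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be non-negative")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be at least 100")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be non-negative")
        if self.triplet_candidates not in ("de", "intersected"):
            raise ConfigError("triplet_candidates must be 'de' or 'intersected'")
        if self.triplet_targets not in ("all", "ligands"):
            raise ConfigError("triplet_targets must be 'all' or 'ligands'")
        if self.ligands and len(self.ligands) != 2:
            raise ConfigError("exactly two ligand gene ids are required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{Path(path).name}: config must be a mapping")
        raw.update(overrides)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
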