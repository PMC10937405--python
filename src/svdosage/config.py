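"""Analysis thresholds and their provenance-free defaults.

Every cutoff used by the pipeline lives here so a run is fully auditable
from its YAML config: the 10-kb SV-gene linking radius, the 1.5-fold
dosage rule, the panel/population expression filters, the group-size
eligibility minima, the 20-kb cis window, permutation counts, the LTR
molecular-clock rate and the CpG-depth floor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


@dataclass
class AnalysisConfig:
    link_radius_bp: int = 10_000
    context_flank_bp: int = 3_000
    fold_threshold: float = 1.5
    tpm_min_panel: float = 1.0
    frac_min_panel: float = 0.60
    min_genomes_per_group: int = 4
    tpm_min_pop: float = 5.0
    frac_min_pop: float = 0.30
    min_genotyped: int = 60
    min_group_size: int = 10
    cis_window_bp: int = 20_000
    perm_n_methylation: int = 10_000
    perm_n_tfbs: int = 1_000
    substitution_rate_per_site_per_year: float = 1.3e-8
    alpha: float = 0.05
    egwas_alpha: float = 1.0e-10
    top_fraction: float = 0.05
    high_methylation_threshold: float = 0.80
    min_cpg_depth: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            self.link_radius_bp,
            self.context_flank_bp,
            self.min_genomes_per_group,
            self.min_genotyped,
            self.min_group_size,
            self.cis_window_bp,
            self.perm_n_methylation,
            self.perm_n_tfbs,
            self.min_cpg_depth,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        fracs = (
            self.frac_min_panel,
            self.frac_min_pop,
            self.alpha,
            self.top_fraction,
            self.high_methylation_threshold,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")
        if self.substitution_rate_per_site_per_year <= 0:
            raise ValueError("substitution rate must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the full parameter set, for log lines."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
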