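"""Run configuration: every tunable threshold of the pipeline in one object.

Defaults are the published working values of the panel-design protocol:
site filters (missing rate < 0.1, site uniformity > 0.25, target rate > 0.5,
all at a simulated nominal depth of 40X), optimizer constraints (mean
adjacent-marker gap <= 0.3 Mbp per chromosome, reinsertions < 1% of the
background set, >= 60% of background SNPs with MAF > 0.05, >= 20% of the
panel in the top MAF class), and probe rules (110 bp, GC in [30%, 70%],
homology count < 3 for background / < 5 for trait loci, up to 2 / 3 probes
per site).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    # site-selection thresholds (strict inequalities, applied at 40X)
    missing_rate_max: float = 0.1
    site_uniformity_min: float = 0.25
    target_rate_min: float = 0.5
    nominal_depth: int = 40

    # panel-optimizer constraints
    max_mean_gap_bp: float = 300_000.0
    reinsertion_budget_frac: float = 0.01
    maf05_share_min: float = 0.60
    top_bin_share_min: float = 0.20

    # probe-design parameters
    probe_length: int = 110
    gc_min: float = 0.30
    gc_max: float = 0.70
    homology_max_background: int = 3   # accept counts strictly below this
    homology_max_trait: int = 5
    max_probes_background: int = 2
    max_probes_trait: int = 3

    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "missing_rate_max": self.missing_rate_max,
            "site_uniformity_min": self.site_uniformity_min,
            "target_rate_min": self.target_rate_min,
            "reinsertion_budget_frac": self.reinsertion_budget_frac,
            "maf05_share_min": self.maf05_share_min,
            "top_bin_share_min": self.top_bin_share_min,
            "gc_min": self.gc_min,
            "gc_max": self.gc_max,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.probe_length < 1:
            raise ValidationError("probe_length must be >= 1")
        if self.nominal_depth < 1:
            raise ValidationError("nominal_depth must be >= 1")
        if self.gc_min > self.gc_max:
            raise ValidationError("gc_min must not exceed gc_max")
        if self.max_mean_gap_bp <= 0:
            raise ValidationError("max_mean_gap_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
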