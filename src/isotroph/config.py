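"""Analysis configuration shared by the CLI and the library entry points."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    enrichment_per_transfer
        Per-mil increase of d15N per trophic transfer. 2.5 by default, with
        2.54 as the commonly used meta-analytic alternative.
    n_permutations
        Permutation count for Mantel-type tests (p resolution 1/(n+1)).
    rng_seed
        Seed for every randomized operation in a run.
    min_diet_n
        Minimum stomachs per species for the diet analyses (N >= 5 filter).
    standardize_habitat
        Column-standardize habitat variables before Euclidean distances.
    ethanol_d13C_offset
        Per-mil d13C correction subtracted to undo ethanol-preservation
        enrichment of liver tissue (0 = off; ~1.5 reported for 95% EtOH).
    tail
        Permutation-test direction: "upper" (default), "lower" or "two-sided".
    """

    enrichment_per_transfer: float = 2.5
    n_permutations: int = 999
    rng_seed: int = 0
    min_diet_n: int = 5
    standardize_habitat: bool = True
    ethanol_d13C_offset: float = 0.0
    tail: str = "upper"

    def __post_init__(self) -> None:
        if not self.enrichment_per_transfer > 0:
            raise ValidationError("enrichment_per_transfer must be > 0")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if self.tail not in ("upper", "lower", "two-sided"):
            raise ValidationError(f"unknown tail {self.tail!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat key/value YAML file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must contain flat key: value pairs")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
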