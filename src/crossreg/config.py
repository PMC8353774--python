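"""Pipeline configuration.

Defaults carry the method's free parameters: 1000 bp promoters, a 1e-5
E-value cutoff, 10% reciprocal-best score tolerance, 15-gene synteny windows
with level thresholds 1/2/3, double-strand scanning, and a 65,536-sequence
IUPAC expansion cap.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class GenomeInput:
    path: str
    species: str
    strain: str = ""


@dataclass
class PipelineConfig:
    genomes: list[GenomeInput] = field(default_factory=list)
    promoter_length: int = 1000
    evalue_threshold: float = 1e-5
    rbh_tolerance: float = 0.10
    synteny_window: int = 15
    synteny_min_common: tuple[int, int, int] = (1, 2, 3)
    reciprocal_mode: str = "symmetric"  # or "strict_reverse"
    scan_strands: str = "both"  # or "forward-only"
    unfold_cap: int = 65536
    condition_vocabulary: Optional[str] = None  # YAML: group -> [subgroups]
    reference_species: Optional[str] = None
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rbh_tolerance < 1):
            raise ValueError("rbh_tolerance must be in [0, 1)")
        if self.scan_strands not in ("both", "forward-only"):
            raise ValueError("scan_strands must be 'both' or 'forward-only'")
        if self.reciprocal_mode not in ("symmetric", "strict_reverse"):
            raise ValueError("reciprocal_mode must be 'symmetric' or 'strict_reverse'")
        self.synteny_min_common = tuple(self.synteny_min_common)  # type: ignore

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        genomes = [GenomeInput(**g) for g in data.pop("genomes", [])]
        try:
            return cls(genomes=genomes, **data)
        except TypeError as exc:
            raise ValueError(f"invalid configuration key in {path}: {exc}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synteny_min_common"] = list(self.synteny_min_common)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def load_vocabulary(self) -> Optional[dict[str, set[str]]]:
        if self.condition_vocabulary is None:
            return None
        with open(self.condition_vocabulary) as fh:
            raw = yaml.safe_load(fh)
        return {group: set(subs or []) for group, subs in raw.items()}
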