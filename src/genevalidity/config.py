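"""Tunable thresholds for the classification and validity rules.

Every numeric rule in the engine is surfaced here so curation policy is
auditable and overridable from one YAML file. Defaults:

* Segregation LOD tiers: >= 3.0 strong (classical genome-wide linkage
  significance), >= 1.5 moderate, >= 0.6 supporting, else none.
* Benign frequency: allele frequency > 5e-4 with allele count >= 5 in any
  cohort is stand-alone-strength benign evidence for rare cardiac disease;
  adjust per condition prevalence.
* Absence in controls: 0 alleles in >= 10,000 total control alleles is
  moderate pathogenic evidence.
* Case count: >= 3 unrelated probands with a specific matching phenotype
  is moderate evidence (down-weighted to supporting while the
  gene-condition link is unestablished).
* Phenotype match: a case manifests a condition when its id matches or
  >= 60% of the condition's feature tokens appear in the case's features.
* Strong gene-condition link: >= 3 unrelated probands with pathogenic
  variants; 1-2 such probands in a proven gene is an emerging link.
* Panel yield: a gene is required on a panel when flagged substantial or
  when its yield fraction is >= 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class RunConfig:
    # segregation LOD tier cut points (log10 odds)
    lod_strong: float = 3.0
    lod_moderate: float = 1.5
    lod_supporting: float = 0.6
    # population frequency rules
    benign_allele_frequency: float = 5e-4
    benign_min_allele_count: int = 5
    absence_min_allele_number: int = 10_000
    # case-count criterion
    case_count_min_probands: int = 3
    # phenotype partial-match fraction of condition feature tokens
    phenotype_match_fraction: float = 0.6
    # gene-condition strength thresholds (unrelated pathogenic-variant probands)
    strong_min_probands: int = 3
    # panel validation
    yield_fraction_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (self.lod_strong >= self.lod_moderate >= self.lod_supporting > 0):
            raise ValueError("LOD tier cut points must be positive and ordered")
        if not (0 < self.benign_allele_frequency < 1):
            raise ValueError("benign_allele_frequency must be in (0, 1)")
        if not (0 < self.phenotype_match_fraction <= 1):
            raise ValueError("phenotype_match_fraction must be in (0, 1]")
        if self.strong_min_probands < 1:
            raise ValueError("strong_min_probands must be >= 1")
        if not (0 <= self.yield_fraction_threshold <= 1):
            raise ValueError("yield_fraction_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(asdict(cls()))
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


DEFAULT_CONFIG = RunConfig()
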