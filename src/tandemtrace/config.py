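"""Pipeline configuration: every analysis threshold in one place.

Defaults mirror the study conditions: 2.5 kb locus flanks, 10 kb unique
sequence for unlinked loci, 100% bootstrap for transposition calls,
i-evalue 1e-3 (general domains) / 1e-10 (CAZymes), bit-score bins of 50
with 25 sampled per bin.  Thresholds are echoed into output headers for
provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    flank_bp: int = 2500
    locus_max_gap: int = 20_000
    gap_open: int = 25
    gap_extend: int = 10
    free_end_gaps: bool = True
    recency_alpha: float = 0.05
    recency_floor: float = 50.0
    recency_n_shuffles: int = 100
    min_support: int = 100
    min_unique_bp: int = 10_000
    min_locus_coverage: float = 0.5
    i_evalue_general: float = 1e-3
    i_evalue_cazyme: float = 1e-10
    bin_width: float = 50.0
    n_bins: int = 10
    per_bin: int = 25
    telomere_min_copies: int = 3
    telomere_window: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def header_lines(self) -> list[str]:
        return [f" {k}={v}" for k, v in asdict(self).items()]

    def scoring_params(self):
        from .align import ScoringParams

        return ScoringParams(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            free_end_gaps=self.free_end_gaps,
        )
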