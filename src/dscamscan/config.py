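"""Pipeline configuration: thresholds, paths, calibration settings.

Defaults follow the detection rules the pipeline reproduces: ten gene-search
block profiles with a six-of-ten ordered co-occurrence rule at E <= 0.001;
37 longer Dscam-hv profiles requiring strictly more than ten ordered matches
at E < 0.01; exon-variant scanning at E <= 0.001; the best two hits per
profile retained.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    # paths
    alignment: Optional[str] = None
    boundaries: Optional[str] = None
    genome: Optional[str] = None
    anchors_bed: Optional[str] = None
    tree: Optional[str] = None
    out_dir: str = "dscamscan_out"
    # block extraction
    n_blocks: int = 10
    block_min_len: int = 25
    block_max_len: int = 50
    pseudocount: float = 1.0
    # thresholds
    gene_e_cutoff: float = 0.001
    hv_e_cutoff: float = 0.01
    exon_e_cutoff: float = 0.001
    k_min: int = 6
    hv_n_blocks: int = 37
    hv_k_min: int = 11          # "> 10" read strictly
    top_m: int = 2
    same_strand: bool = True
    # calibration
    calibration_n_samples: int = 1000
    calibration_sample_len: int = 100
    seed: int = 0
    # misc
    genetic_code: int = 1
    gap_penalty: float = 1e-4

    def validate(self) -> None:
        for name in ("gene_e_cutoff", "hv_e_cutoff", "exon_e_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (1 <= self.k_min <= self.n_blocks):
            raise ValidationError("need 1 <= k_min <= n_blocks")
        if not (1 <= self.hv_k_min <= self.hv_n_blocks):
            raise ValidationError("need 1 <= hv_k_min <= hv_n_blocks")
        if self.top_m < 1:
            raise ValidationError("top_m must be >= 1")
        if self.calibration_n_samples < 100:
            raise ValidationError("calibration_n_samples must be >= 100")

    def resolved(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(),
                                             sort_keys=True))
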