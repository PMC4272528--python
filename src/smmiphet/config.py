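"""Pipeline configuration: every analysis threshold in one place.

Defaults are the thresholds the analysis is defined by: phred >= 30 base
quality, >= 30x deduplicated depth, homopolymer runs of 4, 5% allele balance,
recurrence in 2 controls, 30-60% GC, 15 eligible probes per gene, copy
estimates above 3 (amplified) and 6 (highly amplified), 30% high-AF and 1%
trace bands.  ``print-config`` dumps this object and is the single source of
truth for a run's thresholds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # pileup / candidate calling
    min_base_quality: int = 30
    min_depth: int = 30
    homopolymer_run: int = 4
    min_ab: float = 0.05
    # somatic filters
    control_min_ab: float = 0.05
    control_min_samples: int = 2
    # copy number
    gc_min: float = 0.30
    gc_max: float = 0.60
    control_min_coverage: int = 30
    min_probes: int = 15
    amp_threshold: float = 3.0
    high_amp_threshold: float = 6.0
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 2
    use_segmented_R: bool = True
    # dedup
    max_tag_distance: int = 1
    dedup_method: str = "random"
    # heterogeneity
    high_af: float = 0.30
    trace_af: float = 0.01
    trace_min_reads: int = 2
    low_band_requires_filters: bool = True
    hypermutation_multiple: float = 5.0
    # control selection: "auto" picks the control with the lowest allele
    # fraction of known pathogenic (COSMIC) variants; or name a sample id
    universal_control: str = "auto"
    # contamination warning threshold for the control diagnostic
    contamination_warn_af: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
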