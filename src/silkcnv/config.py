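"""Pipeline configuration.

All tunable parameters of the CNV discovery workflow live here, with the
values used in the four-silkworm study as defaults: a per-caller FDR of 0.01
driving bin size and gain/loss thresholds, the 3-standard-deviation /
chi-square (p < 0.05) high-confidence filter, and the ratio-caller settings
(150 control reads per window, smoothing lambda 7).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Parameters of the read-depth CNV pipeline.

    Attributes
    ----------
    fdr_alpha : per-bin significance used both for bin-size selection and the
        gain/loss thresholds (two-sided; alpha/2 per tail).
    detection_power : minimum probability that a single 1-copy or 3-copy bin
        crosses its threshold; drives bin-size selection.
    sd_multiplier : ``k`` in the ``|RD - mean| > k * SD`` high-confidence gate.
    chi_sq_alpha : p-value cutoff of the per-region chi-square gate.
    loess_span : LOESS span (fraction of bins) of the GC correction.
    read_num : control read-starts per window of the ratio caller.
    smoothing_lambda : total-variation smoothing strength of the ratio caller.
    perm_alpha, n_perm, min_width : circular-binary-segmentation settings.
    read_length : read length in bp assumed for depth-rate conversions.
    ploidy_offset : integer offset added to the modal copy number when the
        ratio caller rescales its fitted levels (0 = modal level is diploid).
    """

    fdr_alpha: float = 0.01
    detection_power: float = 0.95
    sd_multiplier: float = 3.0
    chi_sq_alpha: float = 0.05
    loess_span: float = 0.3
    read_num: int = 150
    smoothing_lambda: float = 7.0
    perm_alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    read_length: int = 100
    ploidy_offset: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "chi_sq_alpha", "detection_power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.read_num < 1:
            raise ValueError("read_num must be >= 1")
        if self.smoothing_lambda < 0:
            raise ValueError("smoothing_lambda must be >= 0")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration (used in run manifests)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
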