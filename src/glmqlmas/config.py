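"""Run-level configuration shared by the differential-expression stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass
class RunConfig:
    """Knobs of the DE / ranking stages.

    alpha
        Significance level applied to adjusted p-values (default 0.05).
    mas_M, mas_A
        Exponents of the Magnitude-Altitude Score
        ``|log2FC|^M * |log10 p_adj|^A`` (default 1, 1: effect size and
        significance weighted equally).
    lfc_threshold
        |log2FC| gate for calling a gene up/down (default 1).
    resampling_R
        Number of balanced resampling iterations (default 500).
    consistency_min
        Minimum same-direction significant iterations for a biomarker
        candidate (default ceil(R/2)).
    correction
        Multiple-testing correction: "BH" or "bonferroni".
    """

    alpha: float = 0.05
    mas_M: float = 1.0
    mas_A: float = 1.0
    lfc_threshold: float = 1.0
    resampling_R: int = 500
    consistency_min: int | None = None
    seed: int = 0
    correction: str = "BH"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mas_M < 0 or self.mas_A < 0:
            raise ValueError("MAS exponents must be non-negative")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.resampling_R < 1:
            raise ValueError("resampling_R must be positive")
        if self.consistency_min is None:
            self.consistency_min = math.ceil(self.resampling_R / 2)
        if not 0 < self.consistency_min <= self.resampling_R:
            raise ValueError("consistency_min must be in [1, resampling_R]")
        if self.correction not in ("BH", "bonferroni"):
            raise ValueError("correction must be 'BH' or 'bonferroni'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in known})
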