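"""Pipeline configuration.

A single flat configuration object carries every tunable of the analysis
chain: the spike-in anchoring target, the percentile used for the final
between-array scaling, the regularized t-test hyper-parameters (window
width, prior weight, baseline subtraction) and the FDR threshold.  The
defaults reproduce the published analysis settings of the study design
this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Settings for the full normalization + differential-testing chain.

    Parameters
    ----------
    anchor_spike_name
        Name of the spike-in used to anchor each array's log-signal scale.
    anchor_log_value
        log10 relative concentration of the anchor spike; after anchoring,
        the anchor's log10 signal equals this value in every sample.
    percentile
        Percentile (of non-control probe intensities) to which each sample
        is scaled after interpolation to the concentration scale.
    bayes_window
        Width (odd integer) of the intensity-ranked sliding window used to
        estimate the background variance of the regularized t-test.
    bayes_weight
        Prior weight ``v0`` given to the background variance (pseudo-count
        of prior observations).
    baseline_subtraction
        Constant subtracted from linear-scale signals before log transform
        and testing; values are floored at 1.0 afterwards.
    alpha
        Benjamini-Hochberg FDR threshold for calling significance.
    rng_seed
        Seed for any stochastic step downstream of configuration.
    """

    anchor_spike_name: str = "E1A_r60_a20"
    anchor_log_value: float = 3.83
    percentile: float = 75.0
    bayes_window: int = 101
    bayes_weight: float = 8.0
    baseline_subtraction: float = 10.0
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bayes_window <= 0 or self.bayes_window % 2 == 0:
            raise ValueError(
                f"bayes_window must be a positive odd integer, got {self.bayes_window}"
            )
        if self.bayes_weight <= 0:
            raise ValueError(f"bayes_weight must be positive, got {self.bayes_weight}")
        if self.baseline_subtraction < 0:
            raise ValueError(
                f"baseline_subtraction must be non-negative, got {self.baseline_subtraction}"
            )
        if not 0 < self.percentile <= 100:
            raise ValueError(f"percentile must lie in (0, 100], got {self.percentile}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key-value (YAML) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
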