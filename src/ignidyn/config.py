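"""Run configuration for the ignition pipeline.

Defaults mirror the study conditions: 4-TR ignition window, 0.01–0.09 Hz
band, 10,000 permutations at α = 0.05 with FDR q = 0.05, 10 mRMR features
and k ∈ {2..5} neighbours.  The event threshold θ defaults to 1 z-unit, the
canonical choice for point-process reductions of BOLD signals.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    threshold_theta: float = 1.0
    window_trs: int = 4
    n_permutations: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_features: int = 10
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    seed: int = 0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.09
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if self.window_trs < 1:
            raise ParameterError("window_trs must be >= 1")
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if not self.k_range or min(self.k_range) < 1:
            raise ParameterError("k_range must be non-empty with min >= 1")
        nyquist = 0.5 / self.tr_seconds
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ParameterError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz infeasible "
                f"for TR={self.tr_seconds}s (Nyquist {nyquist:.4g} Hz)"
            )
        for name in ("alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load from a YAML (or JSON — YAML is a superset) mapping."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d
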