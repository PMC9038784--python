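"""Experimental design: sampling scheme of the diel co-culture experiment.

The reference design samples a diatom/bacterium co-culture every 6 h over
48 h (9 timepoints, 3 biological replicates), with the first sample taken at
midnight so that successive samples fall at midnight, mid-morning (06:00),
noon and mid-afternoon (18:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .light import IrradianceProfile

__all__ = ["ExperimentDesign", "sample_label", "parse_sample_label"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling layout of the time-series experiment.

    ``clock_offset`` maps elapsed time to clock hours: the first sample is
    collected at clock hour ``clock_offset`` (default 0 = midnight).
    """

    n_timepoints: int = 9
    sampling_interval: float = 6.0
    window: float = 48.0
    n_replicates: int = 3
    clock_offset: float = 0.0
    light: IrradianceProfile = field(default_factory=IrradianceProfile)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.n_timepoints < 2:
            raise ValueError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        span = (self.n_timepoints - 1) * self.sampling_interval
        if abs(span - self.window) > 1e-9:
            raise ValueError(
                f"(n_timepoints - 1) x sampling_interval = {span} "
                f"does not equal window = {self.window}"
            )

    @property
    def times(self) -> np.ndarray:
        """Elapsed sampling times in hours from the first sample (0-based)."""
        return np.arange(self.n_timepoints) * self.sampling_interval

    @property
    def clocks(self) -> np.ndarray:
        """Clock hour of each timepoint in [0, 24)."""
        return np.mod(self.times + self.clock_offset, 24.0)

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.n_replicates

    def sample_labels(self) -> list[str]:
        """Column labels ``t{HH}_rep{j}``, ordered timepoint-major."""
        return [
            sample_label(t, j + 1)
            for t in self.times
            for j in range(self.n_replicates)
        ]


def sample_label(elapsed_hours: float, replicate: int) -> str:
    return f"t{int(round(elapsed_hours)):02d}_rep{replicate}"


def parse_sample_label(label: str) -> tuple[float, int]:
    """Parse ``t{HH}_rep{j}`` into (elapsed hours, replicate index)."""
    try:
        tpart, rpart = label.split("_")
        if not (tpart.startswith("t") and rpart.startswith("rep")):
            raise ValueError
        return float(tpart[1:]), int(rpart[3:])
    except ValueError as exc:
        raise ValueError(
            f"sample label {label!r} does not match 't{{HH}}_rep{{j}}'"
        ) from exc
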