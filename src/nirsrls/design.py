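"""Block-design stimulation paradigm.

A block paradigm alternates a stimulus period with a rest period, repeated
``n_blocks`` times after an initial quiet baseline. The paradigm fixes the
frequencies at which an evoked hemodynamic response concentrates its power:
the fundamental 1/(stim+rest) and its harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BlockDesign"]


@dataclass(frozen=True)
class BlockDesign:
    """Timing of a block-design run: baseline, then stim/rest blocks.

    The default paradigm is 20 s stimulus / 20 s rest, 10 blocks, after a
    200 s baseline — a ~7 minute run with a 0.025 Hz stimulation frequency.
    """

    stim_duration_s: float = 20.0
    rest_duration_s: float = 20.0
    n_blocks: int = 10
    baseline_duration_s: float = 200.0

    def __post_init__(self) -> None:
        if self.stim_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("stimulus and rest durations must be > 0")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.baseline_duration_s < 0:
            raise ValueError("baseline duration must be >= 0")

    @property
    def block_duration_s(self) -> float:
        return self.stim_duration_s + self.rest_duration_s

    @property
    def task_duration_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.baseline_duration_s + self.task_duration_s

    @property
    def fundamental_hz(self) -> float:
        """Stimulation frequency: one cycle per stim+rest block."""
        return 1.0 / self.block_duration_s

    def harmonic_hz(self, k: int) -> float:
        """Frequency of the k-th harmonic of the block paradigm (k=1 is the fundamental)."""
        if k < 1:
            raise ValueError("harmonic index must be >= 1")
        return k * self.fundamental_hz
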