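"""Staged pre-training curriculum for the automated go/no-go task.

Naive animals are shaped over seven phases that successively add the
conditions of a full discrimination trial: at first any head insertion into
the odor port is rewarded; across phases the pre-sampling occupancy
threshold rises, a lick criterion appears, the reward is delayed toward the
end of the 2 s response window, the reward volume shrinks, and the
inter-trial interval grows.  An animal advances out of a phase only after a
minimal number of completed trials AND at least 80% correct within its last
20 completed trials; after the final phase it enters odor discrimination.

Fields printed as ranges ramp linearly over the phase's minimal trial
number, then clamp at the end value.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import NamedTuple, Union

__all__ = [
    "PhaseParams",
    "EffectiveParams",
    "CurriculumState",
    "DISCRIMINATION",
    "DEFAULT_CURRICULUM",
    "phase_parameters",
    "PROGRESSION_WINDOW",
    "PROGRESSION_ACCURACY",
]

#: Sentinel phase label once all pre-training phases are complete.
DISCRIMINATION = "DISCRIMINATION"

#: Progression rule: >= 80% correct within the last 20 completed trials.
PROGRESSION_WINDOW = 20
PROGRESSION_ACCURACY = 0.80

Ramp = tuple[float, float]
Scalar = Union[float, Ramp]


@dataclasses.dataclass(frozen=True)
class PhaseParams:
    """One row of the curriculum table.

    Ramped fields are (start, end) tuples interpolated over ``min_trials``;
    scalars apply throughout the phase.
    """

    phase_id: int
    presampling_threshold: float  # fraction of the 500 ms pre-period occupied
    lick_criterion: int  # number of 500 ms response blocks with >= 1 lick
    reward_delay_ms: Scalar
    min_trials: int
    reward_ul: Scalar
    iti_s: Scalar

    def __post_init__(self) -> None:
        if not 0.0 <= self.presampling_threshold <= 1.0:
            raise ValueError(f"presampling_threshold must be in [0,1]: {self}")
        if not 0 <= self.lick_criterion <= 3:
            raise ValueError(f"lick_criterion must be in [0,3]: {self}")
        if self.min_trials <= 0:
            raise ValueError(f"min_trials must be positive: {self}")


#: Default seven-phase curriculum (thresholds as fractions, delays in ms,
#: volumes in microliters, ITIs in seconds).
DEFAULT_CURRICULUM: tuple[PhaseParams, ...] = (
    PhaseParams(1, 0.0, 0, 0.0, 50, 20.0, (0.0, 0.5)),
    PhaseParams(2, 0.0, 0, 0.0, 50, (20.0, 10.5), (0.5, 3.9)),
    PhaseParams(3, 0.125, 0, (21.0, 500.0), 100, 10.0, 1.0),
    PhaseParams(4, 0.25, 0, (500.0, 1980.0), 100, 10.0, 1.0),
    PhaseParams(5, 0.50, 1, 2000.0, 100, 10.0, 1.0),
    PhaseParams(6, 0.75, 2, 2000.0, 100, 10.0, 1.0),
    PhaseParams(7, 0.875, 3, 2000.0, 100, 15.0, 1.0),
)


class EffectiveParams(NamedTuple):
    threshold: float
    criterion: int
    delay_ms: float
    reward_ul: float
    iti_s: float


def _interp(value: Scalar, index: int, min_trials: int) -> float:
    if isinstance(value, tuple):
        start, end = value
        frac = min(index, min_trials) / min_trials
        return start + (end - start) * frac
    return float(value)


def phase_parameters(phase: PhaseParams, trial_index: int) -> EffectiveParams:
    """Effective parameters at a given completed-trial index within a phase.

    Ramped fields interpolate linearly from start (index 0) to end (index
    ``min_trials``) and clamp thereafter.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    return EffectiveParams(
        threshold=phase.presampling_threshold,
        criterion=phase.lick_criterion,
        delay_ms=_interp(phase.reward_delay_ms, trial_index, phase.min_trials),
        reward_ul=_interp(phase.reward_ul, trial_index, phase.min_trials),
        iti_s=_interp(phase.iti_s, trial_index, phase.min_trials),
    )


class CurriculumState:
    """Per-animal progression through the pre-training phases.

    Tracks completed trials in the current phase and a rolling window of the
    last 20 completed-trial results.  Aborted entries never count.  The
    phase index is monotone non-decreasing; there is no demotion.
    """

    def __init__(
        self,
        animal_id: str,
        curriculum: tuple[PhaseParams, ...] = DEFAULT_CURRICULUM,
        start_at_discrimination: bool = False,
    ) -> None:
        if [p.phase_id for p in curriculum] != list(
            range(1, len(curriculum) + 1)
        ):
            raise ValueError("curriculum phases must be numbered 1..n in order")
        self.animal_id = animal_id
        self.curriculum = curriculum
        self._phase_pos = len(curriculum) if start_at_discrimination else 0
        self.trials_completed_in_phase = 0
        self.window: deque[bool] = deque(maxlen=PROGRESSION_WINDOW)

    @property
    def phase_id(self) -> int | str:
        if self._phase_pos >= len(self.curriculum):
            return DISCRIMINATION
        return self.curriculum[self._phase_pos].phase_id

    @property
    def in_discrimination(self) -> bool:
        return self._phase_pos >= len(self.curriculum)

    @property
    def phase(self) -> PhaseParams:
        if self.in_discrimination:
            raise ValueError("animal has completed pre-training")
        return self.curriculum[self._phase_pos]

    def record_completed(self, correct: bool) -> None:
        """Register one completed (non-aborted) trial and advance if due.

        Advancement requires both gates: completed trials in phase >=
        ``min_trials`` and at least 16 of the last 20 completed trials
        correct.  The window and counter reset on phase entry.
        """
        if self.in_discrimination:
            return
        self.trials_completed_in_phase += 1
        self.window.append(correct)
        need = int(PROGRESSION_ACCURACY * PROGRESSION_WINDOW)
        if (
            self.trials_completed_in_phase >= self.phase.min_trials
            and len(self.window) == PROGRESSION_WINDOW
            and sum(self.window) >= need
        ):
            self._phase_pos += 1
            self.trials_completed_in_phase = 0
            self.window.clear()
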