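"""Trial state machine for RFID-gated go/no-go training.

A trial begins when an animal breaks the IR beams of the odor port.  It is
only started if a complete RFID read identifies the animal; otherwise the
controller reverts to baseline and logs an aborted entry.  A started trial
runs a 500 ms pre-sampling period during which port occupancy must exceed
the phase threshold before the final valve opens; the odor (clean air
during pre-training) is then applied for at most 2 s or until the animal
retracts its head.  Licking is evaluated in four 500 ms blocks of the
response window; hits are rewarded with water, misses and false alarms
extend the 1 s inter-trial interval by a 3 s penalty.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
from typing import Protocol

import numpy as np

from .curriculum import (
    DEFAULT_CURRICULUM,
    CurriculumState,
    EffectiveParams,
    PhaseParams,
    phase_parameters,
)
from .sequencing import Scheduler, SequenceParams, TrialLabel

__all__ = [
    "Outcome",
    "TrialTimings",
    "TrialRecord",
    "TrialStart",
    "Controller",
    "AgentInterface",
    "evaluate_presampling",
    "classify_outcome",
    "classify_pretraining",
    "schedule_iti",
]


class Outcome(enum.Enum):
    HIT = "HIT"  # S+ and lick response -> reward
    MISS = "MISS"  # S+ and no lick response
    FALSE_ALARM = "FALSE_ALARM"  # S- and lick response -> time penalty
    CORRECT_REJECTION = "CORRECT_REJECTION"  # S- and no lick response
    ABORTED = "ABORTED"  # incomplete RFID or failed pre-sampling


@dataclasses.dataclass(frozen=True)
class TrialTimings:
    """Fixed trial-structure timings (milliseconds unless noted)."""

    presampling_ms: int = 500
    odor_max_ms: int = 2000
    response_block_ms: int = 500
    base_iti_s: float = 1.0
    penalty_s: float = 3.0
    prepulse_ms: int = 120

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @property
    def n_response_blocks(self) -> int:
        return self.odor_max_ms // self.response_block_ms


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """One completed or aborted trial as written to the event log."""

    timestamp: _dt.datetime  # trial start, ms precision
    animal_id: str
    phase: str  # "1".."7" or "DISCRIMINATION"
    trial_label: TrialLabel | None  # None during pre-training (clean air)
    odor_id: str  # "" in pre-training
    presampling_occupancy: float
    lick_blocks: int
    head_retract_ms: int | None  # ms from final-valve opening; None = stayed
    outcome: Outcome
    reward_ul: float
    iti_s: float
    block_id: int | None = None
    block_index: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.presampling_occupancy <= 1.0:
            raise ValueError("presampling_occupancy must be in [0,1]")
        if (self.reward_ul > 0) != (self.outcome is Outcome.HIT):
            raise ValueError("reward_ul > 0 iff outcome is HIT")


@dataclasses.dataclass
class TrialStart:
    """Context for a trial whose RFID gate has been passed."""

    t: float  # seconds since session start
    animal_id: str
    state: CurriculumState


class AgentInterface(Protocol):
    """What the controller needs from the animal (or its simulation)."""

    def presampling_occupancy(self, threshold: float) -> float:
        """Fraction of the 500 ms pre-period with the beam broken."""

    def respond(
        self, label: TrialLabel | None, criterion: int
    ) -> tuple[int, int | None]:
        """(lick_blocks in 0..4, head_retract_ms or None) for this trial."""


def evaluate_presampling(
    occupancy_trace: np.ndarray,
    threshold: float,
    timings: TrialTimings = TrialTimings(),
    sample_rate_hz: int = 1000,
) -> bool:
    """Gate the final valve on pre-sampling port occupancy.

    ``occupancy_trace`` holds beam-state samples (truthy = beam broken) over
    exactly the 500 ms pre-period at ``sample_rate_hz``.  Returns True (PASS)
    iff the occupied fraction is >= ``threshold``; a threshold of 0 passes
    any trace.
    """
    expected = timings.presampling_ms * sample_rate_hz // 1000
    trace = np.asarray(occupancy_trace)
    if trace.ndim != 1 or trace.size != expected:
        raise ValueError(
            f"occupancy trace must hold {expected} samples, got {trace.size}"
        )
    return bool(np.mean(trace.astype(bool)) >= threshold)


def classify_outcome(label: TrialLabel, lick_blocks: int, lick_criterion: int) -> Outcome:
    """Map a discrimination response onto the signal-detection taxonomy.

    A "lick response" requires at least max(criterion, 1) of the four 500 ms
    response blocks to contain a lick contact.
    """
    if not 0 <= lick_blocks <= 4:
        raise ValueError("lick_blocks must be in [0,4]")
    if not 0 <= lick_criterion <= 3:
        raise ValueError("lick_criterion must be in [0,3]")
    licked = lick_blocks >= max(lick_criterion, 1)
    if label is TrialLabel.S_PLUS:
        return Outcome.HIT if licked else Outcome.MISS
    return Outcome.FALSE_ALARM if licked else Outcome.CORRECT_REJECTION


def classify_pretraining(lick_blocks: int, lick_criterion: int) -> Outcome:
    """Pre-training has no S-: a completed trial is correct (HIT) iff it
    satisfies the lick criterion (criterion 0 means no lick is required)."""
    if not 0 <= lick_blocks <= 4:
        raise ValueError("lick_blocks must be in [0,4]")
    return Outcome.HIT if lick_blocks >= lick_criterion else Outcome.MISS


def schedule_iti(outcome: Outcome, base_iti_s: float, penalty_s: float = 3.0) -> float:
    """Inter-trial interval: base after correct trials, base + penalty after
    any false response (Miss or False Alarm).  Aborted entries impose no ITI
    and are a contract violation here."""
    if outcome is Outcome.ABORTED:
        raise ValueError("aborted entries do not schedule an ITI")
    if outcome in (Outcome.MISS, Outcome.FALSE_ALARM):
        return base_iti_s + penalty_s
    return base_iti_s


class Controller:
    """Execute trials and drive each animal's curriculum state.

    The controller owns per-animal :class:`CurriculumState`, the label
    scheduler used once an animal reaches discrimination, and the odor
    assignment.  It is deterministic: all stochasticity lives in the agent.
    """

    def __init__(
        self,
        cohort: list[str],
        curriculum: tuple[PhaseParams, ...] = DEFAULT_CURRICULUM,
        scheduler: Scheduler | None = None,
        timings: TrialTimings = TrialTimings(),
        discrimination_reward_ul: float = 15.0,
        splus_odor: dict[str, str] | None = None,
        sminus_odor: dict[str, str] | None = None,
        start_time: _dt.datetime | None = None,
        skip_pretraining: bool = False,
    ) -> None:
        if len(set(cohort)) != len(cohort):
            raise ValueError("duplicate animal ids in cohort")
        self.timings = timings
        self.curriculum = curriculum
        self.discrimination_reward_ul = discrimination_reward_ul
        self.scheduler = scheduler or Scheduler(SequenceParams())
        self.splus_odor = splus_odor or {}
        self.sminus_odor = sminus_odor or {}
        self.start_time = start_time or _dt.datetime(2024, 1, 1, 0, 0, 0)
        self.states: dict[str, CurriculumState] = {
            a: CurriculumState(a, curriculum, start_at_discrimination=skip_pretraining)
            for a in cohort
        }
        for a in cohort:
            self.scheduler.register(a)

    # -- trial lifecycle ---------------------------------------------------

    def begin_trial(self, t: float, rfid_animal_id: str | None) -> TrialStart | TrialRecord:
        """Gate trial start on a complete RFID read.

        ``rfid_animal_id`` is the identified animal, or None for an
        incomplete/absent read, in which case the port entry is logged as
        ABORTED (no ITI penalty) and the controller returns to baseline.
        """
        if rfid_animal_id is None:
            return self._aborted_record(t, animal_id="", occupancy=0.0)
        if rfid_animal_id not in self.states:
            raise KeyError(f"RFID read for unregistered animal {rfid_animal_id!r}")
        return TrialStart(t, rfid_animal_id, self.states[rfid_animal_id])

    def run_trial(self, start: TrialStart, agent: AgentInterface) -> TrialRecord:
        """Run one trial from the pre-sampling gate to the ITI decision.

        Emits exactly one record.  In pre-training the stimulus is clean air
        (``trial_label`` None); in discrimination the label comes from the
        scheduler and odor identity from the counterbalance assignment.
        """
        state = start.state
        if state.in_discrimination:
            eff = EffectiveParams(
                threshold=self.curriculum[-1].presampling_threshold,
                criterion=self.curriculum[-1].lick_criterion,
                delay_ms=float(self.timings.odor_max_ms),
                reward_ul=self.discrimination_reward_ul,
                iti_s=self.timings.base_iti_s,
            )
        else:
            eff = phase_parameters(state.phase, state.trials_completed_in_phase)

        occupancy = agent.presampling_occupancy(eff.threshold)
        if occupancy < eff.threshold:
            return self._aborted_record(start.t, start.animal_id, occupancy)

        if state.in_discrimination:
            block_id, block_index = self.scheduler.cursor(start.animal_id)
            label = self.scheduler.draw_next(start.animal_id)
            odor_id = (
                self.splus_odor.get(start.animal_id, "odor_A")
                if label is TrialLabel.S_PLUS
                else self.sminus_odor.get(start.animal_id, "odor_B")
            )
        else:
            label, odor_id, block_id, block_index = None, "", None, None

        lick_blocks, head_retract_ms = agent.respond(label, eff.criterion)
        if head_retract_ms is not None:
            head_retract_ms = min(int(head_retract_ms), self.timings.odor_max_ms)

        if label is None:
            outcome = classify_pretraining(lick_blocks, eff.criterion)
        else:
            outcome = classify_outcome(label, lick_blocks, eff.criterion)

        reward = eff.reward_ul if outcome is Outcome.HIT else 0.0
        iti = schedule_iti(outcome, eff.iti_s, self.timings.penalty_s)
        record = TrialRecord(
            timestamp=self._stamp(start.t),
            animal_id=start.animal_id,
            phase=str(state.phase_id),
            trial_label=label,
            odor_id=odor_id,
            presampling_occupancy=round(occupancy, 6),
            lick_blocks=lick_blocks,
            head_retract_ms=head_retract_ms,
            outcome=outcome,
            reward_ul=reward,
            iti_s=iti,
            block_id=block_id,
            block_index=block_index,
        )
        state.record_completed(outcome in (Outcome.HIT, Outcome.CORRECT_REJECTION))
        return record

    # -- helpers -----------------------------------------------------------

    def trial_span_s(self, record: TrialRecord) -> float:
        """Port-holding time of one entry: pre-sampling + odor/response
        window + ITI lockout (aborted entries release the port at once)."""
        if record.outcome is Outcome.ABORTED:
            return 0.2
        return (
            self.timings.presampling_ms / 1000.0
            + self.timings.odor_max_ms / 1000.0
            + record.iti_s
        )

    def _stamp(self, t: float) -> _dt.datetime:
        ms = round(t * 1000.0)
        return self.start_time + _dt.timedelta(milliseconds=ms)

    def _aborted_record(
        self, t: float, animal_id: str, occupancy: float
    ) -> TrialRecord:
        phase = "" if not animal_id else str(self.states[animal_id].phase_id)
        return TrialRecord(
            timestamp=self._stamp(t),
            animal_id=animal_id,
            phase=phase,
            trial_label=None,
            odor_id="",
            presampling_occupancy=round(occupancy, 6),
            lick_blocks=0,
            head_retract_ms=None,
            outcome=Outcome.ABORTED,
            reward_ul=0.0,
            iti_s=0.0,
        )
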