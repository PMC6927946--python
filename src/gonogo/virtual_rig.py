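"""Virtual rig: stochastic mouse agents and a synthetic olfactometer.

The rig lets the controller, sequencer and analysis run end-to-end at desk
scale.  Agents initiate trials as an inhomogeneous Poisson process with an
hourly (circadian) rate profile, compete for the single odor port, and
respond according to an exponential learning rule: the probability of a
lick response to the rewarded odor rises from ``h0`` to ``h_inf`` and the
probability of responding to the unrewarded odor falls from ``f0`` to
``f_inf``, both with time constant ``tau`` in units of completed
discrimination trials,

    p_splus(n)  = h_inf - (h_inf - h0) * exp(-n / tau)
    p_sminus(n) = f_inf + (f0 - f_inf) * exp(-n / tau)

The olfactometer model produces odor-concentration pulse traces with a
per-valve onset latency and time-to-peak, amplitude proportional to the
commanded dilution fraction, and additive Gaussian detector noise.
"""

from __future__ import annotations

import dataclasses
import heapq
import math

import numpy as np

from .controller import Controller, Outcome, TrialRecord, TrialTimings
from .curriculum import DEFAULT_CURRICULUM, PhaseParams
from .sequencing import (
    Scheduler,
    SequenceParams,
    TrialLabel,
    assign_counterbalance,
)

__all__ = [
    "AgentParams",
    "Agent",
    "OlfactometerModel",
    "PulseTrace",
    "nocturnal_profile",
    "learning_probability",
    "sample_initiations",
    "simulate_cohort",
    "synth_odor_trace",
]


def nocturnal_profile(
    light_rate: float = 5.0, dark_rate: float = 17.0, peak_rate: float = 30.0,
    peak_hour: int = 21,
) -> np.ndarray:
    """Hourly trial-initiation rates (trials/h) for a nocturnal animal.

    Dark phase 18:00-06:00 is elevated, with a single peak hour (default the
    fourth hour of the dark phase).  Defaults integrate to roughly 280
    initiations/day, in the typical 200-400 trials/day range.
    """
    lam = np.full(24, light_rate, dtype=float)
    dark = [(18 + k) % 24 for k in range(12)]
    lam[dark] = dark_rate
    lam[peak_hour % 24] = peak_rate
    return lam


@dataclasses.dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one virtual mouse.

    ``h0``/``h_inf`` are initial/asymptotic lick probabilities on S+ trials,
    ``f0``/``f_inf`` on S- trials; ``tau`` is the learning time constant in
    completed discrimination trials.  ``pretrain_lick_prob`` is the chance
    of satisfying a nonzero lick criterion during pre-training.
    """

    h0: float = 0.5
    h_inf: float = 0.98
    f0: float = 0.5
    f_inf: float = 0.02
    tau: float = 120.0
    activity_rate: tuple[float, ...] = tuple(nocturnal_profile())
    p_rfid_fail: float = 0.05
    p_presample_fail: float = 0.05
    pretrain_lick_prob: float = 0.95

    def __post_init__(self) -> None:
        for name in ("h0", "h_inf", "f0", "f_inf", "p_rfid_fail",
                     "p_presample_fail", "pretrain_lick_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if len(self.activity_rate) != 24 or any(r < 0 for r in self.activity_rate):
            raise ValueError("activity_rate must be 24 non-negative hourly rates")


def learning_probability(params: AgentParams, n: int, label: TrialLabel) -> float:
    """Lick probability after ``n`` completed discrimination trials."""
    decay = math.exp(-n / params.tau)
    if label is TrialLabel.S_PLUS:
        return params.h_inf - (params.h_inf - params.h0) * decay
    return params.f_inf + (params.f0 - params.f_inf) * decay


class Agent:
    """Stateful virtual mouse satisfying the controller's agent interface."""

    def __init__(self, params: AgentParams, rng: np.random.Generator) -> None:
        self.params = params
        self.rng = rng
        self.n = 0  # completed discrimination trials (learning index)

    def presampling_occupancy(self, threshold: float) -> float:
        """Occupied fraction of the pre-period; fails the gate with
        probability ``p_presample_fail`` when a nonzero threshold applies."""
        p = self.params
        if threshold > 0.0 and self.rng.random() < p.p_presample_fail:
            return float(self.rng.uniform(0.0, threshold))
        return float(self.rng.uniform(max(threshold, 0.875), 1.0))

    def respond(
        self, label: TrialLabel | None, criterion: int
    ) -> tuple[int, int | None]:
        """(lick_blocks, head_retract_ms) for one trial.

        Licking animals hold their head in the port for the full response
        window; non-licking animals retract early.
        """
        rng = self.rng
        if label is None:  # pre-training, clean air
            if criterion == 0:
                return 0, None
            licked = rng.random() < self.params.pretrain_lick_prob
            if licked:
                return int(rng.integers(criterion, 5)), None
            return int(rng.integers(0, criterion)), int(rng.uniform(300, 1500))
        p = learning_probability(self.params, self.n, label)
        licked = rng.random() < p
        need = max(criterion, 1)
        if licked:
            return int(rng.integers(need, 5)), None
        return 0, int(rng.uniform(300, 1500))

    def register_completed_discrimination(self) -> None:
        self.n += 1


def sample_initiations(
    activity_rate: tuple[float, ...] | np.ndarray,
    duration_h: float,
    rng: np.random.Generator,
    start_hour: float = 0.0,
) -> np.ndarray:
    """Event times (hours) of an inhomogeneous Poisson process.

    The intensity is piecewise-constant over clock hours, ``activity_rate[h]``
    trials per hour at hour-of-day ``h``; the process starts at clock time
    ``start_hour`` and runs for ``duration_h`` hours.  Returns sorted times
    relative to the start.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    lam = np.asarray(activity_rate, dtype=float)
    times: list[float] = []
    t = 0.0
    while t < duration_h:
        seg = min(1.0 - ((start_hour + t) % 1.0), duration_h - t)
        hour = int((start_hour + t) % 24)
        k = rng.poisson(lam[hour] * seg)
        if k:
            times.extend(t + rng.uniform(0.0, seg, size=k))
        t += seg
    return np.sort(np.asarray(times))


def simulate_cohort(
    config,
    duration_h: float,
    seed: int,
    skip_pretraining: bool = False,
) -> list[TrialRecord]:
    """Discrete-event simulation of a cohort sharing one odor port.

    ``config`` is a :class:`gonogo.config.RunConfig`.  Animals draw
    initiation times from their circadian profile; only one animal can hold
    the port at a time (a blocked initiation retries after an exponential
    delay); each accepted entry passes through the RFID gate and, if
    identified, the controller's full trial state machine.  All randomness
    derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    animal_ids = [a.animal_id for a in config.cohort]
    streams = ss.spawn(len(animal_ids) + 1)
    rig_rng = np.random.Generator(np.random.PCG64(streams[-1]))

    cb = assign_counterbalance(
        [(a.animal_id, a.group) for a in config.cohort],
        config.odor_pair,
        seed=int(ss.generate_state(1)[0] % (2**31)),
    )
    scheduler = Scheduler(
        config.sequencer, seed=int(ss.generate_state(2)[1] % (2**31))
    )
    controller = Controller(
        animal_ids,
        curriculum=config.curriculum,
        scheduler=scheduler,
        timings=config.timings,
        discrimination_reward_ul=config.discrimination_reward_ul,
        splus_odor=cb.splus_odor,
        sminus_odor=cb.sminus_odor,
        start_time=config.start_time,
        skip_pretraining=skip_pretraining,
    )

    agents: dict[str, Agent] = {}
    queue: list[tuple[float, int, str]] = []
    counter = 0
    for aid, stream in zip(animal_ids, streams):
        rng = np.random.Generator(np.random.PCG64(stream))
        params = config.agent_params(aid)
        agents[aid] = Agent(params, rng)
        for t_h in sample_initiations(
            params.activity_rate, duration_h, rng, start_hour=config.start_hour
        ):
            heapq.heappush(queue, (float(t_h) * 3600.0, counter, aid))
            counter += 1

    records: list[TrialRecord] = []
    port_free_at = 0.0
    horizon_s = duration_h * 3600.0
    while queue:
        t, _, aid = heapq.heappop(queue)
        if t >= horizon_s:
            continue
        agent = agents[aid]
        if t < port_free_at:
            # port occupied: drop and retry after an exponential delay
            retry = port_free_at + agent.rng.exponential(config.retry_mean_s)
            if retry < horizon_s:
                counter += 1
                heapq.heappush(queue, (retry, counter, aid))
            continue
        if agent.rng.random() < agent.params.p_rfid_fail:
            rec = controller.begin_trial(t, None)
            rec = dataclasses.replace(rec, animal_id=aid, phase="")
        else:
            start = controller.begin_trial(t, aid)
            rec = controller.run_trial(start, agent)
            if rec.outcome is not Outcome.ABORTED and rec.trial_label is not None:
                agent.register_completed_discrimination()
        records.append(rec)
        port_free_at = t + controller.trial_span_s(rec)
    return records


# -- synthetic olfactometer -------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OlfactometerModel:
    """Synthetic dual-channel olfactometer pulse model.

    Per-valve onset latencies and times-to-peak default to the measured
    behavior of the physical device (onset ~15.91 ms after final-valve
    opening for every reservoir; time-to-peak growing from ~65.4 ms for the
    reservoir nearest the final valve to ~91.4 ms for the farthest).
    Amplitude is ``gain`` times the commanded dilution fraction plus
    additive Gaussian noise.
    """

    onset_latency_ms: tuple[float, ...] = (15.91,) * 6
    time_to_peak_ms: tuple[float, ...] = (65.38, 70.58, 75.78, 80.98, 86.18, 91.38)
    rise_tau_ms: float = 20.0
    decay_tau_ms: float = 2000.0
    gain: float = 1.0
    noise_sd: float = 0.01
    sample_interval_ms: float = 1.0
    duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if len(self.onset_latency_ms) != len(self.time_to_peak_ms):
            raise ValueError("per-valve latency and time-to-peak lists differ")
        for onset, peak in zip(self.onset_latency_ms, self.time_to_peak_ms):
            if not 0 < onset < peak:
                raise ValueError("each valve needs 0 < onset < time_to_peak")
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValueError("time constants must be positive")


@dataclasses.dataclass(frozen=True)
class PulseTrace:
    """Uniformly sampled odor-concentration trace, time zero at final-valve
    opening, concentration in arbitrary detector units."""

    times_ms: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        if self.times_ms.shape != self.concentration.shape:
            raise ValueError("times and concentrations must align")
        if self.times_ms.size >= 2:
            dt = np.diff(self.times_ms)
            if not np.allclose(dt, dt[0]):
                raise ValueError("sampling must be uniform")


def synth_odor_trace(
    model: OlfactometerModel,
    valve_id: int,
    dilution_fraction: float,
    rng: np.random.Generator | None = None,
) -> PulseTrace:
    """Synthesize one odor pulse for a valve at a commanded dilution.

    The rise is a saturating exponential normalized so the concentration
    peaks (at amplitude ``gain * dilution_fraction``) exactly at the valve's
    time-to-peak, followed by a slow exponential decay.  The rise origin is
    placed so that the 10%-of-max crossing — the operational definition of
    odor onset — falls exactly at the valve's configured onset latency.
    Valve ids are 1-based.
    """
    if not 1 <= valve_id <= len(model.onset_latency_ms):
        raise ValueError(
            f"unknown valve_id {valve_id}; model has valves 1..{len(model.onset_latency_ms)}"
        )
    if not 0.0 <= dilution_fraction <= 1.0:
        raise ValueError("dilution_fraction must be in [0,1]")
    onset = model.onset_latency_ms[valve_id - 1]
    t_peak = model.time_to_peak_ms[valve_id - 1]
    tau = model.rise_tau_ms
    times = np.arange(0.0, model.duration_ms, model.sample_interval_ms)
    amp = model.gain * dilution_fraction

    # Solve for the rise origin t0 such that the normalized rise crosses 10%
    # of peak at `onset`:  (1 - exp(-(onset-t0)/tau)) / norm = 0.1
    norm_guess = 1.0 - math.exp(-(t_peak - onset) / tau)  # approx; refined below
    x = -tau * math.log(1.0 - 0.1 * norm_guess)
    t0 = onset - x
    for _ in range(50):  # fixed-point refinement of the normalization
        norm = 1.0 - math.exp(-(t_peak - t0) / tau)
        x = -tau * math.log(1.0 - 0.1 * norm)
        t0_new = onset - x
        if abs(t0_new - t0) < 1e-12:
            t0 = t0_new
            break
        t0 = t0_new
    norm = 1.0 - math.exp(-(t_peak - t0) / tau)

    conc = np.zeros_like(times)
    rising = (times >= t0) & (times <= t_peak)
    conc[rising] = amp * (1.0 - np.exp(-(times[rising] - t0) / tau)) / norm
    falling = times > t_peak
    conc[falling] = amp * np.exp(-(times[falling] - t_peak) / model.decay_tau_ms)
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        conc = conc + rng.normal(0.0, model.noise_sd, size=conc.shape)
    return PulseTrace(times, conc)
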