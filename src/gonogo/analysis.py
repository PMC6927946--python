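"""Behavioral analytics: performance, signal detection, circadian and pulse metrics.

All metrics operate on sequences of :class:`~gonogo.controller.TrialRecord`
(typically read from an event log) or on synthetic odor pulse traces.
"Completed" trials are those with a Hit/Miss/False-Alarm/Correct-Rejection
outcome; aborted entries are excluded from every performance statistic.
Missing values propagate as NaN / None; nothing is silently zero-filled.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .controller import Outcome, TrialRecord
from .sequencing import TrialLabel
from .virtual_rig import AgentParams, PulseTrace, learning_probability

__all__ = [
    "COMPLETED_OUTCOMES",
    "DPrimeInput",
    "PerformanceSeries",
    "CircadianProfile",
    "completed",
    "fraction_correct",
    "dprime",
    "performance_series",
    "trials_to_criterion",
    "circadian_profile",
    "hourly_performance",
    "groupsize_effect",
    "pulse_metrics",
    "daily_counts",
    "fit_learning_model",
]

COMPLETED_OUTCOMES = (
    Outcome.HIT,
    Outcome.MISS,
    Outcome.FALSE_ALARM,
    Outcome.CORRECT_REJECTION,
)

_CORRECT = (Outcome.HIT, Outcome.CORRECT_REJECTION)


def completed(records: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Completed (non-aborted) trials, preserving order."""
    return [r for r in records if r.outcome in COMPLETED_OUTCOMES]


def fraction_correct(records: Sequence[TrialRecord]) -> float:
    """(Hits + correct rejections) / completed trials; NaN when empty."""
    recs = completed(records)
    if not recs:
        return float("nan")
    return sum(r.outcome in _CORRECT for r in recs) / len(recs)


@dataclasses.dataclass(frozen=True)
class DPrimeInput:
    """Outcome counts of a go/no-go session or window."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "DPrimeInput":
        recs = completed(records)
        return cls(
            hits=sum(r.outcome is Outcome.HIT for r in recs),
            misses=sum(r.outcome is Outcome.MISS for r in recs),
            false_alarms=sum(r.outcome is Outcome.FALSE_ALARM for r in recs),
            correct_rejections=sum(
                r.outcome is Outcome.CORRECT_REJECTION for r in recs
            ),
        )


def dprime(counts: DPrimeInput) -> float:
    """Signal-detection discriminability d' = Phi^-1(H) - Phi^-1(F).

    H is the hit rate over S+ trials, F the false-alarm rate over S- trials.
    Extreme rates (0 or 1, where the inverse normal diverges) are clamped to
    [1/(2N), 1 - 1/(2N)] with N the trial count of that response class.
    Returns NaN when either class has no trials.
    """
    n_signal = counts.hits + counts.misses
    n_noise = counts.false_alarms + counts.correct_rejections
    if n_signal == 0 or n_noise == 0:
        return float("nan")
    h = counts.hits / n_signal
    f = counts.false_alarms / n_noise
    h = min(max(h, 1.0 / (2 * n_signal)), 1.0 - 1.0 / (2 * n_signal))
    f = min(max(f, 1.0 / (2 * n_noise)), 1.0 - 1.0 / (2 * n_noise))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


@dataclasses.dataclass(frozen=True)
class PerformanceSeries:
    """Sliding-window performance along an animal's completed trials.

    ``trial_index[i]`` is the (1-based) count of completed trials at the end
    of window ``i``; values are defined only where the window is full.
    """

    trial_index: np.ndarray
    fraction_correct: np.ndarray
    dprime: np.ndarray
    window: int


def performance_series(
    records: Sequence[TrialRecord], window: int = 100
) -> PerformanceSeries:
    """Windowed fraction correct and d' over completed discrimination trials.

    The default 100-trial window matches the granularity of the sequencer's
    balance bins; it is recorded in the result.
    """
    recs = [r for r in completed(records) if r.trial_label is not None]
    n = len(recs)
    if n < window:
        empty = np.empty(0)
        return PerformanceSeries(empty.astype(int), empty, empty, window)
    correct = np.array([r.outcome in _CORRECT for r in recs], dtype=float)
    is_hit = np.array([r.outcome is Outcome.HIT for r in recs], dtype=int)
    is_splus = np.array(
        [r.trial_label is TrialLabel.S_PLUS for r in recs], dtype=int
    )
    is_fa = np.array([r.outcome is Outcome.FALSE_ALARM for r in recs], dtype=int)

    kernel = np.ones(window)
    frac = np.convolve(correct, kernel, mode="valid") / window
    hits = np.convolve(is_hit, kernel, mode="valid")
    splus = np.convolve(is_splus, kernel, mode="valid")
    fas = np.convolve(is_fa, kernel, mode="valid")
    dps = np.array(
        [
            dprime(
                DPrimeInput(
                    hits=int(h),
                    misses=int(s - h),
                    false_alarms=int(fa),
                    correct_rejections=int(window - s - fa),
                )
            )
            for h, s, fa in zip(hits, splus, fas)
        ]
    )
    idx = np.arange(window, n + 1)
    return PerformanceSeries(idx, frac, dps, window)


def trials_to_criterion(
    series: PerformanceSeries, threshold: float, metric: str = "fraction_correct"
) -> int | None:
    """Completed-trial count at which the windowed metric first reaches
    ``threshold``; None if it never does (or the series is shorter than its
    window).  ``metric`` is ``fraction_correct`` or ``dprime``."""
    if metric not in ("fraction_correct", "dprime"):
        raise ValueError(f"unknown metric {metric!r}")
    values = getattr(series, metric)
    above = np.nonzero(values >= threshold)[0]
    if above.size == 0:
        return None
    return int(series.trial_index[above[0]])


@dataclasses.dataclass(frozen=True)
class CircadianProfile:
    """Average fraction of each day's trials per clock hour for one animal."""

    animal_id: str
    hourly_fraction: np.ndarray  # 24-vector, mean over days with activity
    n_days: int


def circadian_profile(
    records: Sequence[TrialRecord], animal_id: str
) -> CircadianProfile:
    """Per-day hourly trial fractions averaged over days with any activity."""
    recs = [
        r for r in completed(records) if r.animal_id == animal_id
    ]
    if not recs:
        return CircadianProfile(animal_id, np.empty(0), 0)
    frame = pd.DataFrame(
        {
            "day": [r.timestamp.date() for r in recs],
            "hour": [r.timestamp.hour for r in recs],
        }
    )
    per_day = (
        frame.groupby(["day", "hour"]).size().unstack(fill_value=0)
        .reindex(columns=range(24), fill_value=0)
    )
    fractions = per_day.div(per_day.sum(axis=1), axis=0)
    return CircadianProfile(
        animal_id, fractions.mean(axis=0).to_numpy(), len(per_day)
    )


def hourly_performance(records: Sequence[TrialRecord]) -> np.ndarray:
    """Fraction correct per clock hour, pooling completed discrimination
    trials across animals and days; NaN for hours with no trials."""
    recs = [r for r in completed(records) if r.trial_label is not None]
    out = np.full(24, np.nan)
    if not recs:
        return out
    hours = np.array([r.timestamp.hour for r in recs])
    correct = np.array([r.outcome in _CORRECT for r in recs], dtype=float)
    for h in range(24):
        mask = hours == h
        if mask.any():
            out[h] = correct[mask].mean()
    return out


def groupsize_effect(
    summaries: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Pearson r, least-squares slope and p-value of a metric vs group size.

    ``summaries`` pairs (group_size, metric), e.g. mean daily accuracy or
    trials per animal; at least 3 distinct group sizes are required.  With
    zero variance in either variable r and p are NaN (the slope is 0 when
    only the metric is constant).
    """
    sizes = np.asarray([s for s, _ in summaries], dtype=float)
    values = np.asarray([v for _, v in summaries], dtype=float)
    if np.unique(sizes).size < 3:
        raise ValueError("need at least 3 distinct group sizes")
    if np.ptp(values) == 0.0:
        return float("nan"), 0.0, float("nan")
    fit = stats.linregress(sizes, values)
    return float(fit.rvalue), float(fit.slope), float(fit.pvalue)


def pulse_metrics(trace: PulseTrace) -> tuple[float, float, float]:
    """(onset_ms, peak_ms, peak_amplitude) of an odor pulse.

    Onset is the first crossing of 10% of the maximal concentration after
    time zero, linearly interpolated between samples; peak is the time of
    the maximum.  Raises on traces without a positive maximum.
    """
    t = np.asarray(trace.times_ms, dtype=float)
    c = np.asarray(trace.concentration, dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least 2 samples")
    i_peak = int(np.argmax(c))
    peak = float(c[i_peak])
    if peak <= 0:
        raise ValueError("trace has no positive maximum; onset undefined")
    level = 0.1 * peak
    above = np.nonzero((c >= level) & (t >= 0))[0]
    if above.size == 0:
        raise ValueError("trace never crosses 10% of maximum after time zero")
    i = int(above[0])
    if i == 0 or c[i] == c[i - 1]:
        onset = float(t[i])
    else:
        frac = (level - c[i - 1]) / (c[i] - c[i - 1])
        onset = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return onset, float(t[i_peak]), peak


def daily_counts(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Completed-trial counts per animal per calendar day.

    Returns a tidy frame with columns ``animal_id``, ``day``, ``trials``;
    empty input yields an empty frame.  Day boundaries are calendar midnight
    of log-local time.
    """
    recs = completed(records)
    if not recs:
        return pd.DataFrame(columns=["animal_id", "day", "trials"])
    frame = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in recs],
            "day": [r.timestamp.date() for r in recs],
        }
    )
    out = frame.groupby(["animal_id", "day"]).size().reset_index(name="trials")
    return out


def fit_learning_model(
    records: Sequence[TrialRecord],
    p0: AgentParams | None = None,
    shared_baseline: bool = True,
) -> dict[str, float]:
    """Recover exponential-learning parameters from a discrimination log.

    Fits lick probabilities p_splus(n) and p_sminus(n) (see
    :func:`gonogo.virtual_rig.learning_probability`) to the per-trial binary
    lick responses of a single animal's completed discrimination trials by
    maximum likelihood.  By default the naive lick probabilities are
    constrained equal (``h0 = f0``): before any learning the animal cannot
    distinguish the stimuli, so its initial response rate cannot depend on
    the label — and without this constraint the time constant is only
    weakly identified.  Returns h0, h_inf, f0, f_inf and tau.
    """
    recs = [r for r in completed(records) if r.trial_label is not None]
    if len(recs) < 100:
        raise ValueError("need at least 100 completed discrimination trials")
    n = np.arange(len(recs), dtype=float)
    licked = np.array(
        [r.outcome in (Outcome.HIT, Outcome.FALSE_ALARM) for r in recs], dtype=float
    )
    splus = np.array([r.trial_label is TrialLabel.S_PLUS for r in recs])

    def model_nll(h0: float, h_inf: float, f0: float, f_inf: float, tau: float) -> float:
        decay = np.exp(-n / tau)
        p = np.where(
            splus,
            h_inf - (h_inf - h0) * decay,
            f_inf + (f0 - f_inf) * decay,
        )
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(licked * np.log(p) + (1 - licked) * np.log(1 - p)))

    start = p0 or AgentParams()
    log_tau_bounds = (0.0, math.log(1e5))
    if shared_baseline:
        def nll(theta: np.ndarray) -> float:
            b, h_inf, f_inf, log_tau = theta
            return model_nll(b, h_inf, b, f_inf, math.exp(log_tau))

        x0 = np.array([start.h0, start.h_inf, start.f_inf, math.log(start.tau)])
        bounds = [(0.0, 1.0)] * 3 + [log_tau_bounds]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        b, h_inf, f_inf, log_tau = res.x
        h0 = f0 = b
    else:
        def nll(theta: np.ndarray) -> float:
            h0, h_inf, f0, f_inf, log_tau = theta
            return model_nll(h0, h_inf, f0, f_inf, math.exp(log_tau))

        x0 = np.array(
            [start.h0, start.h_inf, start.f0, start.f_inf, math.log(start.tau)]
        )
        bounds = [(0.0, 1.0)] * 4 + [log_tau_bounds]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        h0, h_inf, f0, f_inf, log_tau = res.x
    return {
        "h0": float(h0),
        "h_inf": float(h_inf),
        "f0": float(f0),
        "f_inf": float(f_inf),
        "tau": float(math.exp(log_tau)),
        "converged": float(res.success),
    }
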