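"""Analytics: accuracy, d-prime vs a bisection oracle, circadian, pulses."""

import datetime as dt
import math

import numpy as np
import pytest

from gonogo.analysis import (
    CircadianProfile,
    DPrimeInput,
    circadian_profile,
    daily_counts,
    dprime,
    fraction_correct,
    groupsize_effect,
    hourly_performance,
    performance_series,
    pulse_metrics,
    trials_to_criterion,
)
from gonogo.config import AnimalEntry, RunConfig
from gonogo.controller import Outcome, TrialRecord
from gonogo.sequencing import TrialLabel
from gonogo.virtual_rig import AgentParams, PulseTrace, simulate_cohort


def make_record(
    outcome: Outcome,
    label=TrialLabel.S_PLUS,
    t: dt.datetime | None = None,
    animal="m1",
) -> TrialRecord:
    return TrialRecord(
        timestamp=t or dt.datetime(2024, 1, 1, 12, 0, 0),
        animal_id=animal,
        phase="DISCRIMINATION",
        trial_label=label,
        odor_id="A",
        presampling_occupancy=0.9,
        lick_blocks=4 if outcome in (Outcome.HIT, Outcome.FALSE_ALARM) else 0,
        head_retract_ms=None,
        outcome=outcome,
        reward_ul=15.0 if outcome is Outcome.HIT else 0.0,
        iti_s=4.0 if outcome in (Outcome.MISS, Outcome.FALSE_ALARM) else 1.0,
    )


def inverse_normal_bisect(p: float, lo=-10.0, hi=10.0, tol=1e-12) -> float:
    """Independent Phi^-1 via bisection on the error-function CDF."""
    def cdf(x: float) -> float:
        return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))

    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestFractionCorrect:
    def test_all_hits_is_one(self):
        recs = [make_record(Outcome.HIT) for _ in range(20)]
        assert fraction_correct(recs) == 1.0

    def test_nineteen_of_twenty(self):
        recs = [make_record(Outcome.HIT) for _ in range(19)]
        recs.append(make_record(Outcome.MISS))
        assert fraction_correct(recs) == 0.95

    def test_progression_threshold_value(self):
        recs = [make_record(Outcome.HIT) for _ in range(16)]
        recs += [make_record(Outcome.MISS) for _ in range(4)]
        assert fraction_correct(recs) == 0.80

    def test_empty_window_is_missing(self):
        assert math.isnan(fraction_correct([]))

    def test_aborted_entries_never_count(self):
        recs = [make_record(Outcome.HIT)] * 3
        aborted = TrialRecord(
            timestamp=dt.datetime(2024, 1, 1), animal_id="m1", phase="1",
            trial_label=None, odor_id="", presampling_occupancy=0.0,
            lick_blocks=0, head_retract_ms=None, outcome=Outcome.ABORTED,
            reward_ul=0.0, iti_s=0.0,
        )
        assert fraction_correct(recs + [aborted]) == 1.0


class TestDPrime:
    def test_equal_rates_give_zero(self):
        assert dprime(DPrimeInput(50, 50, 50, 50)) == pytest.approx(0.0)

    def test_95_5_matches_closed_form_and_bisection_oracle(self):
        d = dprime(DPrimeInput(95, 5, 5, 95))
        oracle = inverse_normal_bisect(0.95) - inverse_normal_bisect(0.05)
        assert d == pytest.approx(2.0 * inverse_normal_bisect(0.95), abs=1e-9)
        assert d == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("h,f,n", [(80, 20, 100), (60, 30, 90), (99, 1, 100)])
    def test_grid_against_bisection_oracle(self, h, f, n):
        d = dprime(DPrimeInput(h, n - h, f, n - f))
        hh = min(max(h / n, 1 / (2 * n)), 1 - 1 / (2 * n))
        ff = min(max(f / n, 1 / (2 * n)), 1 - 1 / (2 * n))
        oracle = inverse_normal_bisect(hh) - inverse_normal_bisect(ff)
        assert d == pytest.approx(oracle, abs=1e-9)

    def test_swapping_rates_negates(self):
        a = dprime(DPrimeInput(90, 10, 20, 80))
        b = dprime(DPrimeInput(20, 80, 90, 10))
        assert a == pytest.approx(-b)

    def test_perfect_performance_is_finite_after_clamping(self):
        d = dprime(DPrimeInput(100, 0, 0, 100))
        assert math.isfinite(d)
        assert d == pytest.approx(2.0 * inverse_normal_bisect(1 - 1 / 200), abs=1e-9)

    def test_empty_class_is_missing(self):
        assert math.isnan(dprime(DPrimeInput(0, 0, 5, 5)))

    def test_depends_only_on_outcome_counts_not_odor_identity(self):
        recs = (
            [make_record(Outcome.HIT)] * 40
            + [make_record(Outcome.MISS)] * 10
            + [make_record(Outcome.FALSE_ALARM, label=TrialLabel.S_MINUS)] * 5
            + [make_record(Outcome.CORRECT_REJECTION, label=TrialLabel.S_MINUS)] * 45
        )
        relabeled = [
            TrialRecord(
                **{
                    **r.__dict__,
                    "odor_id": "B" if r.odor_id == "A" else "A",
                }
            )
            for r in recs
        ]
        assert dprime(DPrimeInput.from_records(recs)) == pytest.approx(
            dprime(DPrimeInput.from_records(relabeled))
        )
        assert fraction_correct(recs) == fraction_correct(relabeled)


class TestTrialsToCriterion:
    def test_series_always_above_reaches_at_first_full_window(self):
        recs = [make_record(Outcome.HIT) for _ in range(150)]
        series = performance_series(recs, window=100)
        assert trials_to_criterion(series, 0.95) == 100

    def test_never_reached_is_none(self):
        recs = [make_record(Outcome.MISS) for _ in range(150)]
        series = performance_series(recs, window=100)
        assert trials_to_criterion(series, 0.95) is None

    def test_window_larger_than_series_is_none(self):
        recs = [make_record(Outcome.HIT) for _ in range(50)]
        series = performance_series(recs, window=100)
        assert trials_to_criterion(series, 0.5) is None

    def test_monotone_in_threshold_leniency(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(600):
            p = 1.0 - 0.5 * math.exp(-i / 100)
            correct = rng.random() < p
            label = TrialLabel.S_PLUS if i % 2 else TrialLabel.S_MINUS
            if label is TrialLabel.S_PLUS:
                recs.append(make_record(Outcome.HIT if correct else Outcome.MISS))
            else:
                recs.append(
                    make_record(
                        Outcome.CORRECT_REJECTION if correct else Outcome.FALSE_ALARM,
                        label=label,
                    )
                )
        series = performance_series(recs, window=100)
        strict = trials_to_criterion(series, 0.95)
        lenient = trials_to_criterion(series, 0.85)
        assert lenient is not None
        assert strict is None or lenient <= strict

    def test_faster_learner_reaches_criterion_sooner(self):
        counts = {}
        for tau in (60.0, 240.0):
            cfg = RunConfig(
                cohort=[AnimalEntry("m1")],
                agents=AgentParams(
                    tau=tau, p_rfid_fail=0.0, p_presample_fail=0.0
                ),
            )
            recs = simulate_cohort(cfg, 24.0 * 6, seed=13, skip_pretraining=True)
            series = performance_series(recs, window=100)
            counts[tau] = trials_to_criterion(series, 0.95)
        assert counts[60.0] is not None and counts[240.0] is not None
        assert counts[60.0] < counts[240.0]


class TestCircadian:
    def test_single_hour_activity(self):
        t0 = dt.datetime(2024, 1, 1, 20, 15)
        recs = [make_record(Outcome.HIT, t=t0 + dt.timedelta(minutes=i)) for i in range(10)]
        prof = circadian_profile(recs, "m1")
        assert prof.hourly_fraction[20] == pytest.approx(1.0)
        assert prof.hourly_fraction.sum() == pytest.approx(1.0)

    def test_uniform_activity(self):
        recs = [
            make_record(Outcome.HIT, t=dt.datetime(2024, 1, 1, h, 30))
            for h in range(24)
        ]
        prof = circadian_profile(recs, "m1")
        assert np.allclose(prof.hourly_fraction, 1 / 24)

    def test_daily_fractions_sum_to_one_over_multiple_days(self):
        rng = np.random.default_rng(3)
        recs = []
        for day in range(4):
            for _ in range(rng.integers(5, 30)):
                t = dt.datetime(2024, 1, 1 + day, int(rng.integers(24)), 30)
                recs.append(make_record(Outcome.HIT, t=t))
        prof = circadian_profile(recs, "m1")
        assert prof.n_days == 4
        assert prof.hourly_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_animal_yields_empty_profile(self):
        prof = circadian_profile([make_record(Outcome.HIT)], "ghost")
        assert prof.hourly_fraction.size == 0
        assert prof.n_days == 0

    def test_no_hour_effect_with_hour_independent_policy(self):
        """The agents' response rule ignores clock time, so hourly accuracy
        shows no hour effect (the null circadian-performance result).  Uses a
        stationary (fully trained) policy so no learning trend confounds."""
        from scipy.stats import chi2_contingency

        from gonogo.controller import Outcome

        cfg = RunConfig(
            cohort=[AnimalEntry("m1"), AnimalEntry("m2")],
            agents=AgentParams(
                h0=0.9, h_inf=0.9, f0=0.1, f_inf=0.1,
                p_rfid_fail=0.0, p_presample_fail=0.0,
            ),
        )
        recs = simulate_cohort(cfg, 24.0 * 4, seed=17, skip_pretraining=True)
        hp = hourly_performance(recs)
        assert np.isfinite(hp).sum() == 24
        table = np.zeros((24, 2))
        for r in recs:
            if r.trial_label is None or r.outcome is Outcome.ABORTED:
                continue
            correct = r.outcome in (Outcome.HIT, Outcome.CORRECT_REJECTION)
            table[r.timestamp.hour, 0 if correct else 1] += 1
        keep = table.sum(axis=1) > 0
        _, p, _, _ = chi2_contingency(table[keep])
        assert p > 0.001


class TestGroupSize:
    def test_exactly_linear_decreasing_is_minus_one(self):
        data = [(5, 0.99), (10, 0.97), (15, 0.95), (18, 0.938)]
        r, slope, p = groupsize_effect(data)
        assert r == pytest.approx(-1.0)
        assert slope < 0

    def test_constant_metric_has_undefined_correlation(self):
        r, slope, p = groupsize_effect([(5, 0.9), (10, 0.9), (15, 0.9)])
        assert math.isnan(r)

    def test_toy_table_matches_hand_computed_pearson(self):
        data = [(3.0, 10.0), (5.0, 9.0), (8.0, 7.0), (12.0, 6.0), (18.0, 2.0)]
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        oracle_r = cov / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        oracle_slope = cov / ((x - x.mean()) ** 2).sum()
        r, slope, _ = groupsize_effect(data)
        assert r == pytest.approx(oracle_r, abs=1e-12)
        assert slope == pytest.approx(oracle_slope, abs=1e-12)

    def test_too_few_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            groupsize_effect([(5, 0.9), (10, 0.8)])


class TestPulseMetrics:
    def test_linear_ramp_onset_at_ten_percent(self):
        t = np.arange(0.0, 101.0)
        c = t / 100.0  # 0 -> max over 100 ms
        onset, peak, amp = pulse_metrics(PulseTrace(t, c))
        assert onset == pytest.approx(10.0)
        assert peak == 100.0
        assert amp == 1.0

    def test_step_function_onset_at_step(self):
        t = np.arange(0.0, 50.0)
        c = np.where(t >= 17, 1.0, 0.0)
        onset, _, _ = pulse_metrics(PulseTrace(t, c))
        assert onset == pytest.approx(17.0, abs=1.0)

    def test_flat_zero_trace_rejected(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            pulse_metrics(PulseTrace(t, np.zeros_like(t)))


class TestDailyCounts:
    def test_empty_log_gives_empty_table(self):
        table = daily_counts([])
        assert table.empty

    def test_three_days_of_ten(self):
        recs = []
        for day in range(3):
            for i in range(10):
                t = dt.datetime(2024, 2, 1 + day, 10, i)
                recs.append(make_record(Outcome.HIT, t=t))
        table = daily_counts(recs)
        assert len(table) == 3
        assert (table["trials"] == 10).all()

    def test_counts_conserve_completed_total(self, cohort_run):
        table = daily_counts(cohort_run)
        n_completed = sum(
            r.outcome is not Outcome.ABORTED for r in cohort_run
        )
        assert table["trials"].sum() == n_completed
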