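# Methods

`gonogo` re-implements, in software only, the control logic and analytics of
an automated home-cage training system in which group-housed, RFID-tagged
mice learn a go/no-go odor discrimination at a single shared odor port.
Everything that in the physical rig is hardware — IR beams, the RFID
antenna, olfactometer valves, the lick sensor, the water pump, the animals
themselves — is represented by a virtual rig so the full pipeline can be
exercised and tested at desk scale.

## Trial state machine

A port entry (IR beam break) opens an RFID search. Only a complete tag read
starts a trial; an incomplete or absent read aborts the entry, with no
inter-trial interval and no effect on the animal's curriculum. A started
trial proceeds through:

1. **Pre-sampling** (500 ms): the fraction of 1 kHz beam-state samples with
   the beam broken must reach the phase's threshold before the final valve
   opens. The threshold is read as a fraction of time because the protocol
   states it as a percentage with no other unit; a failed gate aborts the
   trial without penalty (penalizing it would conflate motivation with
   performance, so aborted entries also never enter the progression window).
2. **Odor/response window** (at most 2000 ms): the stimulus stays on until
   the animal retracts its head or 2 s elapse. The window is partitioned
   into four 500 ms blocks; a block counts as licked if at least one lick
   contact falls inside it. A "lick response" requires at least
   max(criterion, 1) counting blocks, so criterion 0 (early phases) still
   defines a response as one licked block for classification purposes.
3. **Outcome and ITI**: S+ with a lick response is a Hit (rewarded); S+
   without is a Miss; S− with a response is a False Alarm; S− without is a
   Correct Rejection. Misses and False Alarms add a 3 s penalty to the 1 s
   base inter-trial interval. The reward in discrimination is 15 µl, the
   final pre-training value, delivered at the end of the response window.

All trial arithmetic uses integer milliseconds; wall-clock timestamps exist
only at the event-log boundary.

## Curriculum

Seven pre-training phases shape task compliance before any odor is
presented (the stimulus is clean air throughout pre-training). Per phase:
pre-sampling threshold 0, 0, 12.5, 25, 50, 75, 87.5 %; lick criterion 0, 0,
0, 0, 1, 2, 3 blocks; reward delay 0, 0, 21–500, 500–1980, 2000, 2000,
2000 ms; minimal trials 50, 50, 100, 100, 100, 100, 100; reward 20, 20–10.5,
10, 10, 10, 10, 15 µl; ITI 0–0.5, 0.5–3.9, 1, 1, 1, 1, 1 s. Ranged entries
ramp linearly over the phase's minimal trial count and clamp afterwards (the
protocol prints ranges without a schedule; a linear ramp is the simplest
monotone interpolation).

Progression requires both gates at once: at least the phase's minimal number
of completed trials, and at least 16 of the last 20 completed trials correct
(80%). In pre-training, "correct" means the completed trial met its lick
criterion (criterion 0 phases therefore count every completed trial as
correct — without an S− there is nothing else correctness could mean); in
discrimination it means Hit or Correct Rejection. There is no demotion. A
flawless performer thus exits phase 1 after exactly 50 completed trials and
finishes all pre-training after exactly 600, the sum of the minimal trial
counts — both are acceptance checks.

## Sequencing

Discrimination labels come in blocks of 1000 with exactly 50 S+ in every
consecutive 100-trial bin ("approximately 50" is implemented as exactly 50:
the strictest reading, it keeps the reward base rate unbiased and the
invariant testable) and no more than 3 consecutive identical labels,
evaluated across bin boundaries over the whole block (runs do not carry
across blocks; each block is validated standalone). A block is served
strictly in order and regenerated only when fully consumed.

Generation walks the block position by position, choosing uniformly among
the labels that are feasible at that point: a label is feasible if its bin
budget is not exhausted, it does not extend the trailing run past the cap,
and the remaining labels of the bin can still be arranged within the cap
(x remaining same-labels fit iff x ≤ (max_run − r) + y·max_run given run r
and y other-labels, and symmetrically y ≤ (x+1)·max_run). Dead ends are
only possible through a bin boundary; the generator then restarts the whole
block, with a 10,000-restart bound before raising a configuration error.
Infeasible parameter sets (e.g. bin 4, 3 S+, max run 1) are rejected up
front by the majority/minority packing condition. The generator is a pure
function of its parameters including the seed.

Each animal consumes its own independent block stream (the protocol is
silent on sharing; independent streams avoid cross-animal stimulus
correlation), with per-block seeds derived deterministically from the
scheduler seed, the animal index and the block counter. Odor→S+ assignment
is counterbalanced within each treatment group to within one animal.

## Virtual rig

**Learning agents.** The probability of a lick response follows an
exponential approach indexed by completed discrimination trials n (not wall
time, matching how learning curves are plotted per trial):
p₊(n) = h∞ − (h∞ − h0)·e^(−n/τ) on S+ and p₋(n) = f∞ + (f0 − f∞)·e^(−n/τ)
on S−. Defaults h0 = f0 = 0.5 (a naive animal cannot tell the odors apart,
so its initial response rate cannot depend on the label), h∞ = 0.98,
f∞ = 0.02 (sustained accuracy ≈ 0.98, in line with reported long-run
performance), τ = 120 trials (criterion crossing within a few hundred
trials, the reported order of magnitude). Licking agents hold their head in
the port for the full window; non-licking agents retract early (uniform
300–1500 ms). RFID reads fail with probability 0.05 and, when a nonzero
threshold applies, pre-sampling fails with probability 0.05 — both modest
rates chosen once as plausible for the hardware, not fitted to anything.

**Activity.** Trial initiations are an inhomogeneous Poisson process with a
piecewise-constant hourly intensity. The default profile is nocturnal —
5/h in the light phase, 17/h in the dark phase (18:00–06:00) with a 30/h
peak in the fourth dark hour — integrating to ≈ 280 initiations/day, inside
the typical 200–400 trials/day range. A single port serves the whole cage:
an initiation that finds the port occupied is dropped and retried after an
exponential delay (mean 60 s), which reproduces the direction (not the
magnitude) of the mild per-animal trial-count decrease in larger cohorts.
All randomness in a simulation derives from one seed via per-animal
substreams.

**Olfactometer.** Each of six odor reservoirs ("valves") has an onset
latency (default 15.91 ms for all) and a time-to-peak (65.38 → 91.38 ms,
increasing with distance from the final valve). A pulse rises as a
saturating exponential (τ_rise = 20 ms) normalized to peak exactly at the
time-to-peak with amplitude gain × dilution fraction, then decays slowly
(τ = 2 s); additive Gaussian detector noise (sd 0.01 in units of the
full-scale gain) is applied last. Because odor onset is *defined* as the
10%-of-maximum crossing, the model back-computes the rise origin so that a
noise-free trace crosses 10% exactly at the configured latency — the model
is calibrated in the same convention the metric measures, and the
onset-recovery test closes that loop to within one 1 ms sample.

## Analytics

- **Fraction correct**: (Hits + Correct Rejections) / completed trials;
  empty windows are NaN, never zero.
- **d′** = Φ⁻¹(H) − Φ⁻¹(F) with hit rate H over S+ trials and false-alarm
  rate F over S− trials, each clamped to [1/(2N), 1 − 1/(2N)] for its own
  class count N so perfect performance stays finite (the standard
  correction; the original analysis does not state one). Tested against an
  independent bisection inversion of the normal CDF to 1e−9.
- **Windowed series** use a 100-trial sliding window by default — the
  protocol plots per-trial curves without naming a window, and 100 matches
  the sequencer's bin granularity; the window size is recorded in outputs.
  Trials-to-criterion is the completed-trial count at the first window
  reaching threshold (0.95 fraction correct, or d′ ≥ 3), aborted entries
  excluded; never reached is None.
- **Circadian profile**: per-day hourly trial fractions (each day summing
  to 1) averaged over days with activity; day boundary is calendar midnight
  of log-local time, dark phase annotated 18:00–06:00. Hourly performance
  pools completed trials per clock hour.
- **Group-size effect**: Pearson r, least-squares slope and p of a metric
  against group size; constant input yields NaN, reported as such.
- **Learning-model fit**: per-trial binary lick responses are fit by
  maximum likelihood (L-BFGS-B on bounded parameters, τ optimized in log
  space). By default the naive baseline is shared (h0 = f0) — the same
  argument as above — because with both baselines free, τ is only weakly
  identified and single-realization estimates scatter widely.

## Problem sizes and what the tests show

Simulated checks run at desk scale: single-animal runs of 4–10 simulated
days (≈ 1000–2800 trials) and a five-animal, three-day cohort; the
τ-recovery check uses three fixed seeds of ≈ 2700 discrimination trials
each and requires the mean recovered τ within 20% of truth. The whole
suite runs in a few seconds.

The virtual rig emulates trial structure, circadian initiation, port
contention, RFID dropouts and exponential learning. It does not emulate
sniffing dynamics, body-weight or water-balance homeostasis, day-to-day
motivation drift, odor-specific salience, or inter-animal interactions
beyond port occupancy — so passing tests validate the control logic and
analytics, not any claim about real animals. Real-animal quantities
(trials-to-criterion means, group-size regression slopes) are explicitly
out of reproduction scope; the rig only reproduces their direction where a
mechanism (the shared port) implies it.

## Known limitations

- The run-cap feasibility check is exact per bin but only necessary across
  bin boundaries; pathologically tight multi-bin geometries fail at
  generation time (bounded restarts, then a configuration error) rather
  than up front.
- The agent's lick-block count is drawn uniformly above/below criterion
  rather than from a lick-train model; `lick_blocks` is therefore useful
  for classification, not for microstructure analysis.
- Event logs are kept wholly in memory; multi-month multi-cohort logs
  (~10⁵ rows) are fine, but there is no streaming reader.
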