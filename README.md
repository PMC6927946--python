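# gonogo

Computational core of an automated, RFID-gated go/no-go olfactory training
system for group-housed mice — implemented entirely in software, with a
built-in virtual rig, so the control logic and analytics can be developed,
tested and reasoned about without hardware or animals.

In a go/no-go task the animal licks at a rewarded odor (S+) and withholds
licking to an unrewarded one (S−), giving the four signal-detection
outcomes Hit / Miss / False Alarm / Correct Rejection. In the automated
home cage, animals live with free access to a single odor port: an IR beam
break plus a complete RFID read starts a trial; a 500 ms pre-sampling gate
must be passed before the final valve opens; the odor stays on for at most
2 s; a Hit earns a water reward, and any false response (Miss or False
Alarm) extends the 1 s inter-trial interval by a 3 s penalty. A seven-phase
pre-training curriculum shapes naive animals up to this structure, with
progression requiring a minimum trial count and ≥ 80% accuracy over the
last 20 completed trials.

The package provides:

- **`gonogo.sequencing`** — constrained pseudo-random S+/S− blocks
  (1000 trials, exactly 50 S+ per 100-trial bin, no run longer than 3),
  per-animal block scheduling, and counterbalanced odor→S+ assignment.
- **`gonogo.controller` / `gonogo.curriculum`** — the trial state machine,
  outcome classification, ITI scheduling, and the staged curriculum with
  its ramped parameters.
- **`gonogo.virtual_rig`** — stochastic learning agents (exponential
  learning of lick probability with time constant τ in trials), circadian
  Poisson trial initiation with single-port contention, RFID dropouts, and
  a synthetic olfactometer with per-valve onset latency, time-to-peak and
  dilution-proportional amplitude.
- **`gonogo.analysis`** — windowed fraction correct and
  d′ = Φ⁻¹(H) − Φ⁻¹(F) (with 1/(2N) extreme-rate clamping),
  trials-to-criterion, circadian activity profiles, hourly performance,
  group-size correlations, odor-pulse onset/peak metrics, daily trial
  counts, and maximum-likelihood recovery of the learning parameters.
- **`gonogo.eventlog` / `gonogo.config` / `gonogo.cli`** — a versioned CSV
  (or JSON-lines) event-log format with strict validation, YAML run
  configuration, and a `gonogo` command with `simulate`, `gen-sequence`,
  `analyze` and `validate` subcommands.

## Worked example

Simulate one animal on odor discrimination for ten days and quantify its
learning:

```python
from gonogo.config import AnimalEntry, RunConfig
from gonogo.virtual_rig import AgentParams, simulate_cohort
from gonogo.analysis import (performance_series, trials_to_criterion,
                             DPrimeInput, dprime, fraction_correct)

cfg = RunConfig(cohort=[AnimalEntry("m1", group="wt")],
                agents=AgentParams(tau=120.0))
records = simulate_cohort(cfg, duration_h=240.0, seed=5, skip_pretraining=True)
series = performance_series(records, window=100)
print("completed trials:", sum(r.outcome.value != "ABORTED" for r in records))
print("trials to 0.95 fraction correct:", trials_to_criterion(series, 0.95))
print("trials to d' >= 3:", trials_to_criterion(series, 3.0, metric="dprime"))
print("final fraction correct:", round(fraction_correct(records[-1000:]), 3))
print("final d':", round(dprime(DPrimeInput.from_records(records[-1000:])), 2))
```

```
completed trials: 2467
trials to 0.95 fraction correct: 353
trials to d' >= 3: 351
final fraction correct: 0.981
final d': 4.15
```

The agent crosses the 0.95 accuracy criterion after 353 completed trials
(a windowed measure: the first 100-trial window whose accuracy reaches
0.95), reaches the d′ ≥ 3 criterion at about the same point, and then holds
~0.98 accuracy — the qualitative signature of successful acquisition:
a few hundred trials to criterion, then stable high performance.

The same pipeline from the shell:

```sh
gonogo simulate --duration 24 --seed 5 --out run.csv   # day of training
gonogo validate run.csv                                # exit 0 iff schema-valid
gonogo analyze run.csv --out tables/ --plots           # summary + figures
gonogo gen-sequence --seed 1 --out block.txt           # one 1000-trial block
gonogo gen-sequence --validate block.txt               # constraint checker
```

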