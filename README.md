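# algalink

Closed-loop simulation of **optical interlink feedback** between two
isolated micro-populations of photoresponsive microalgae.

Two 25-square micro-aquaria (480 um squares joined by 90 um passages)
each hold one species: dish A contains ~400 *Euglena gracilis*-like
swimmers that respond to blue light photophobically (straight swimming
→ on-site tumbling, plus turning back at illumination borders), dish B
contains ~1300 *Chlamydomonas reinhardtii*-like cells that are
photo-*activated* (resting cells resume swimming under blue light).
Each dish is observed by rendering one feedback cycle's swimming traces
into a binary image and counting the covered pixels per square — the
**trace momentum** TM, a 25-vector proxy for local cell activity.  The
two dishes interact *only* through these exchanged TM datasets, which
drive each other's illumination every 1.47 s cycle (0.68 Hz) under one
of two rules:

* **Two-state flipping** — with group TM sums TM_I and TM_II over two
  fixed 12-square groups, when

      |TM_I − TM_II| / (TM_I + TM_II) ≥ T,      T ∈ (0.05, 0.40)

  the TM-dominant group is illuminated in the counter-dish at the next
  step.  This closes a negative feedback through the Euglena escape
  dynamics and produces an autonomous **cell-density oscillation**
  whose period grows with T (≈6.5 min at T = 0.40) with a short
  dish-B→dish-A phase delay (≈0.43 min).
* **Ranking** — dish B is lit on the 12 *lowest*-TM squares of dish A,
  dish A on the 12 *highest*-TM squares of dish B.  This drives
  autonomous **separation and clustering**: the two dishes' activity
  maps become near-perfect mirror images (illumination coincidence
  ≈23 of 25 squares) and the dark squares aggregate into single
  domains.

The package is a tool for studying these designed cell–cell
interactions in silico: agent-based run-and-tumble/two-state motility,
the trace-image TM statistic, both interlink algorithms, the analysis
metrics (period, phase delay, coincidence, duty ratios, domain
clustering, pattern histograms), and a calibration stage that fits the
free behavioural parameters to the published closed-loop observables.

## Worked example

A reduced-scale oscillation run (100 + 325 agents, 400 steps, threshold
0.10) through the Python API:

```python
from algalink import ExperimentConfig, ScheduleConfig, run_experiment
from algalink import oscillation_period, phase_delay

config = ExperimentConfig(
    n_euglena=100, n_chlamy=325, threshold=0.10, seed=11,
    schedule=ScheduleConfig(total_steps=400, warmup_steps=50, cooldown_steps=50),
)
log = run_experiment(config)

period = oscillation_period(log)
delay = phase_delay(log)
print(f"full oscillation period : {period.period_mean:.2f} +- {period.period_sd:.2f} min "
      f"({period.n_cycles} cycles)")
print(f"phase delay B -> A      : {delay.phase_delay_mean:.2f} min")
print(f"dish-B flips            : {[(f.step, f.group) for f in log.dish_flips('B')]}")
```

prints

```
full oscillation period : 1.90 +- 0.42 min (3 cycles)
phase delay B -> A      : 0.23 min
dish-B flips            : [(59, 'II'), (105, 'I'), (131, 'II'), (201, 'I'), (251, 'II'), (283, 'I'), (313, 'II'), (338, 'I')]
```

The dish-B illumination alternates I→II→I… purely because dish A's
Euglena drain out of whichever group is lit; the period here is short
because the reduced populations make the TM ratio noisier and the
threshold low.  At full scale (400/1300 cells, 4000 steps) with the
shipped defaults the period at threshold 0.40 is ≈6.2 min — see below.
A full period is two alternating flips; each listed flip marks the step
at which the new pattern first applied.

The same objects drive the command line:

```sh
algalink run -o myrun --algorithm ranking --seed 3       # simulate
algalink analyze myrun/log.csv -o myrun/metrics --plots  # re-analyse a log
algalink calibrate -o calib                              # refit parameters
```

`run` writes the per-step log CSV (patterns, TM vectors, ratios, flip
events for both dishes), a config echo and a manifest with checksums
sufficient to re-run bit-identically.

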