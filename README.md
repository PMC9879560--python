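# stopsignal

Simulation and analysis of the stop-signal task (SST) with generalized
up/down stop-signal-delay staircases.

The SST measures response inhibition: participants make a speeded
two-choice response to a go stimulus, but on a minority of trials a stop
signal appears after a stop-signal delay (SSD) and the response must be
withheld. The latency of the covert stopping process — the stop-signal
reaction time (SSRT) — is not observable and is estimated under the
independent horse-race model, in which the go and stop processes race and
a response escapes iff the go process finishes before SSD + SSRT.

The package is for researchers who run or analyse SSTs and want to reason
quantitatively about staircase design choices (50 % vs. 66.67 % stopping
accuracy), monitor-refresh timing artefacts, strategic slowing, and the
reliability of SSRT estimates.

## What it computes

**Staircase asymptote.** An up/down staircase that raises the SSD by
`Δ_s` ms after each successful stop and lowers it by `Δ_f` ms after each
failed stop equilibrates where the expected SSD change per stop trial is
zero, `p·Δ_s − (1−p)·Δ_f = 0`, hence at stopping accuracy

```
p* = Δ_f / (Δ_f + Δ_s)
```

The classic symmetric ±50 ms staircase tracks 50 %; a +25/−50 staircase
tracks 66.67 %. Both presets start at SSD = 250 ms.

**Refresh quantization.** Stimulus onsets snap to monitor refreshes. At
60 Hz (16.67 ms frames) an intended SSD of 175 ms is displayed at
183.33 ms; over the 25 ms SSD lattice of the +25/−50 staircase the mean
onset delay is 4.17 ms, so the effective mean post-success step is
29.17 ms and the adjusted asymptote is 50/(50+29.17) = 63.16 %.

**Horse-race simulation.** Seeded sessions and cohorts: ex-Gaussian go
finishing times, zero-truncated-normal SSRTs, optional within-block
linear slowing drift, lapses and choice errors; the session design is
4 phases × 192 trials (two 96-trial blocks, 25 % stop trials), phases
alternating between the two staircases with a reset at each phase.

**SSRT estimation.** The integration method per 96-trial block: with
p = p(respond|signal) and N valid go RTs, SSRT = the ceil(p·N)-th
fastest go RT minus the mean SSD. Go omissions are excluded (an optional
replacement rule substitutes the max go RT). The mean method
(mean go RT − mean SSD) is included for comparison.

**Quality control.** Block exclusion for stop accuracy < 25 % or a
strategic-slowing slope (OLS of go RT on go-trial ordinal) > 2 ms per go
trial; phase exclusion for race-model violations (mean go RT < mean
signal-respond RT), SSRT < 100 ms, or an excluded block; participant
exclusion for go accuracy < 70 % or non-adherence. Plus the Pearson
goodness-of-fit χ² comparing excluded-block counts between staircases.

**Reliability.** Test–retest (phase 1 vs. phase 2 of each staircase) and
cross-staircase Pearson correlations over pairwise-complete participants,
and Table-style descriptives (n, missing, mean, SD, min, max).

## Worked example

```
$ stopsignal predict-staircase --delta-success 25 --delta-fail 50 --refresh-hz 60
asymptote: 0.6667
mean display delay: 4.17 ms
quantization-adjusted asymptote: 0.6316
```

The +25/−50 staircase targets 66.67 % stopping accuracy; on a 60 Hz
monitor its post-success steps are displayed 4.17 ms late on average,
which the step-inflation arithmetic converts into a 63.16 % adjusted
asymptote.

```
$ stopsignal simulate --seed 11 --out trials.csv --n-per-environment 3
wrote 6912 trials (9 participants) to trials.csv
$ stopsignal qc trials.csv --out qc.csv --phases-out phases.csv
slowing-slope exclusions [p50]: 1 blocks
slowing-slope exclusions [p66]: 2 blocks
wrote exclusion report to qc.csv
$ stopsignal report trials.csv --out-prefix demo
staircase_label  n  missing       mean        sd        min        max
            p50 16        2 204.312188 41.984713 111.031667 287.103333
            p66 17        1 221.553137 42.007683 142.140000 311.080000
             pairing grouping  n_pairs  pearson_r  p_value
phase1_vs_phase2_p50  overall        7   0.639984 0.121595
phase1_vs_phase2_p66  overall        8   0.599829 0.115971
    p50_vs_p66_means  overall        9   0.674501 0.046282
```

Nine simulated participants (three per testing environment: individual
lab, group lab, online) each complete a 768-trial session. The report
shows phase-level SSRT descriptives per staircase after exclusions
(means near the generating SSRT distribution, with the +25/−50 staircase
slightly higher), and the test–retest and cross-staircase correlations —
with only 9 participants these are noisy; cohorts of ~75 participants
give r ≈ .55–.75, the range typical of the task.

The same operations are available as a library:

```python
from stopsignal import (ParticipantParams, simulate_session,
                        records_to_frame, estimate_blocks)

params = ParticipantParams(go_mu_ms=400, go_sigma_ms=60, go_tau_ms=120,
                           ssrt_mu_ms=220, ssrt_sigma_ms=40)
trials = records_to_frame(simulate_session(params, seed=1))
print(estimate_blocks(trials)[["phase_index", "block_index", "ssrt_ms"]])
```

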