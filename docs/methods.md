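# Methods

## The race model and what is simulated

Every trial draws a latent go finishing time from an ex-Gaussian
distribution — the convolution of a normal (μ, σ) and an exponential (τ)
— the standard parametric family for reaction times. On stop trials an
independent stopping latency (SSRT) is drawn from a normal (μ_stop,
σ_stop) truncated at zero, and a response is emitted iff the go process
finishes strictly before SSD + SSRT and within the 1,500 ms response
window. Context independence holds by construction: the go draw on a stop
trial comes from the same distribution as on a go trial (the test suite
checks this on the latent draws directly).

The session design is fixed by the task: 4 experimental phases of 192
trials, each split into two 96-trial blocks with 25 % stop trials at
seeded-random positions (no adjacency constraints — the task description
this mirrors does not state any); phases alternate between the two
staircases, the starting staircase is randomized per participant (or
fixed via `SessionDesign.staircase_order`), and each phase resets its
staircase to the 250 ms initial SSD. A 32-trial practice block is
simulated and dropped from output by default.

Additional response processes, all defaulting to realistic or zero
values: a lapse rate (the go process produces no response, independent of
its latency), a choice-error rate (wrong key), a trigger-failure rate
(the stop process fails to start; default 0), and a within-block linear
drift of the go mean (`slowing_slope_ms_per_go_trial`) indexed by the
go-trial ordinal and reset at block boundaries. The drift models
strategic slowing — deliberately lengthening go responses to make
stopping easier — in the same per-block linear form the exclusion
criterion fits, so an injected slope of s ms/go-trial is recovered by the
QC slope estimator with expectation s.

## Staircase algebra and quantization

An up/down staircase with post-success step Δ_s and post-failure step Δ_f
has asymptotic stopping accuracy p* = Δ_f/(Δ_f+Δ_s) (zero expected drift).
SSDs are clamped to [0, 1150] ms — the task itself states no bounds; the
upper bound leaves ~350 ms of the 1,500 ms response window for stopping —
and clamping events are logged.

Stop-signal onsets snap to the first monitor refresh at or after the
intended SSD, with the go signal frame-aligned at t = 0. Frame time is
held as the rational 1000/refresh_hz and comparisons use a 10⁻⁹ ms guard,
so exact multiples are classified exactly and the snapping map is
idempotent. Only the stop signal is quantized; go onsets are taken as
jitter-free. OS/keyboard timing jitter is out of scope.

`effective_asymptote` reproduces the step-inflation arithmetic for a
quantized display: the mean onset delay over the staircase's SSD lattice
(pitch = gcd of steps, start and bounds) is added to Δ_s before applying
the asymptote formula. At 60 Hz this gives the +25/−50 staircase an
effective +29.17 ms step and a 63.16 % adjusted asymptote.

That closed form should be read as a bound-style heuristic, not as the
realized accuracy of a simulated staircase. When the staircase state is
book-kept in *intended* SSDs (the convention here, matching task software
that records intended delays), a telescoping identity pins realized
accuracy to the unadjusted asymptote: Δ_s·S − Δ_f·F equals the net SSD
displacement, which is bounded, so S/(S+F) → Δ_f/(Δ_f+Δ_s) regardless of
quantization. Simulations confirm it (realized quantized p66 accuracy
0.660–0.666 depending on reset schedule, vs. 0.660–0.667 unquantized).
Had the staircase instead stored the quantized onset, every post-success
step in display space would be a whole frame larger (+33.33 ms at 60 Hz)
and accuracy would tend to 50/83.33 = 60 %. The two conventions bracket
the 63.16 % figure; the simulator asserts only the bracket, while the
closed form reproduces the 63.16 % arithmetic exactly. What quantization
unambiguously does produce is a recorded mean SSD ≈ 4.17 ms shorter than
the displayed one, and hence integration-method SSRTs overestimated by
the same amount under the +25/−50 staircase.

## SSRT estimation

Integration method per 96-trial block: p = (failed stops)/(stop trials);
the included go RTs are all responded go trials (omissions excluded);
rank n = ceil(p·N), 1-based, clamped to [1, N] — the rounding convention
is not standardized in the field, and ceil with clamping makes degenerate
blocks (p = 0 or 1) well defined. SSRT = n-th fastest go RT − mean
*intended* SSD. Choice-error responses count as valid go RTs (only the
omission rule is standard); an optional replacement estimator substitutes
the maximum observed go RT for each omission (off by default). The mean
method (mean go RT − mean SSD) is provided for comparison and is
systematically slower than the integration estimate whenever stop
accuracy exceeds 50 %, because the staircase then holds the mean SSD
short relative to the go distribution.

Aggregation: phase SSRT = mean of its two block estimates, defined only
when both blocks survive QC (one excluded block leaves 24 stop trials —
too few). Staircase-level SSRT averages the two phases, giving a single
surviving phase 100 % weight; both excluded ⇒ missing.

## Exclusion rules

All thresholds are strict inequalities — boundary values are retained —
with a 10⁻⁹ guard so that data lying exactly on a threshold (e.g. a
noiseless 2.0 ms/go-trial ramp) are not excluded by float rounding in the
OLS fit. "Mean stop RT" in the race-model check is interpreted as the
mean signal-respond (failed-stop) RT, the standard race-model diagnostic.
The slowing slope regresses go RT on the *go-trial ordinal* (matching its
ms-per-go-trial units), not the overall trial index. The participant
adherence screen (overall stop accuracy < 1 %) is applied before block
QC and is configurable. Excluded-block counts per staircase feed a
two-cell Pearson goodness-of-fit χ² against an equal split (df = 1).

## Synthetic cohorts

The cohort generator draws per-participant parameters from
environment-level normal distributions (clipped to validity). Defaults
encode the three testing environments: mean go RT (μ+τ) ≈ 512 / 533 /
614 ms for individual-lab / group-lab / online, SSRT mean 245 ms with a
40 ms between-participant SD, and slowing-slope means of 0.2 / 0.3 /
0.8 ms per go trial — online participants respond slower and drift more,
the supervision gradient the task literature reports. Each participant
has one SSRT distribution shared by both staircases, so cross-staircase
correlations are attenuated only by estimation noise; simulated
test–retest correlations land in the .5–.8 range typical of the task.

What the generator does **not** emulate: staircase-dependent strategic
slowing (real participants slow more under a 50 % staircase; here the
slope is a participant trait), post-stop-failure sequential slowing,
fatigue or practice trends across phases, and keyboard/browser timing
jitter. Passing tests therefore validate the estimators and pipeline
mechanics under the race model, not those behavioural phenomena.

## Problem sizes and numerics

Simulation-based checks use sizes chosen for stable Monte-Carlo targets:
staircase-convergence checks track ≥ 5,000 stop trials (≈ 210 blocks) and
assert agreement within 2 binomial SEs; integration-method recovery
aggregates ≥ 2,000 stop trials and asserts |bias| < 15 ms against the
mean of the latent SSRT draws (the simulator exposes them per block);
cohort-level reliability properties use 75 participants. All randomness
flows through `numpy.random.Generator` seeded from a single seed
(cohorts spawn child seeds via `SeedSequence`, so any participant's data
are reproducible independently). Truncated-normal SSRTs are drawn by
rejection, exact for the truncation at zero. The trial-table CSV dialect
writes timing at two decimals; round-trips are exact to 0.01 ms.
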