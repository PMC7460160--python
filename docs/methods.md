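# Methods

This note records the models, conventions and design choices behind
`hradapt`, in the order the data flows: signal → controllers → session →
simulator → statistics.

## Signal processing

Raw readings arrive at a nominal 1 Hz as `(t, bpm, device)`. Two physical
wrist bands were used interchangeably in the system this engine was built
for; a stair-stepping calibration test put the second model 9.13 bpm above
the first on average, so that offset is subtracted from every band-2
reading (`CalibrationConfig.band2_offset_bpm`, default 9.13). Simulated
streams bypass calibration.

Cleaning drops empty (NaN) records and suppresses outliers with hard
physiological bounds, default [40, 220] bpm. A distributional outlier test
was deliberately avoided: the bounds are auditable, idempotent, and
sufficient for wrist-optical artifacts (dropouts read as 0, motion spikes
read far above any child's maximum). Cleaning an already-clean stream is a
no-op, and the cleaner reports counts of what it removed.

Scaling maps bpm linearly onto [0, 1] over a configurable range, default
60–200 bpm, clamped at both ends. The reference range is fixed rather than
per-participant: it spans a 5–7-year-old's resting-to-maximal band, it
guarantees the documented [0, 1] codomain for any input, and it keeps the
smoothing weight `w` comparable across participants. A per-participant
(resting, 220 − age) scaling is expressible by passing a different
`ScaleConfig`.

Both controller inputs come from one shared 20-sample ring buffer:
`w` is the mean of the scaled values and `avgHR` the mean of the raw values
over the same window. A session-cumulative `avgHR` would also be coherent,
but a rolling mean keeps the controllers reactive at 1 Hz and needs only
one state object; with fewer than 20 samples the mean is over what is
available. Controllers hold (score and timers still run, difficulty does
not move) until the window has `warmup_samples` readings, default 5,
avoiding a spurious first-tick jump off a one-sample average.

## Controllers

All difficulty rules branch on `avgHR` against `hr_threshold = 95` bpm.
The published branch conditions are strict inequalities on both sides,
leaving equality undefined; this implementation treats `avgHR = 95` as the
high-exertion (easing) branch, erring toward making the game easier. The
105 bpm upper boundary appears in none of the update rules; it is stored
and drives an optional hysteresis mode (harden only below 95, ease only
above 105, hold in between), disabled by default.

**Scenario 1 (flying character).** Distance `d` accrues one unit per tick
below the goal `deltaD`. On goal completion below threshold, statements
execute in their printed order — `deltaD ← deltaD + deltaD·w` first, then
the speed update uses the *new* `deltaD`. The published pseudocode
subtracts at that point (`vh ← vh − deltaD·w`) while its accompanying prose
says the speed is *incremented*; only the increment is consistent with the
rule's purpose (raise effort while HR is low), so the default `intent` mode
adds, and a `literal` mode reproduces the printed sign exactly. Both are
first-class: the replay harness can re-run any log under either mode and
reports the first tick where they differ. The unprinted boundary case
`d = deltaD` is folded into the goal-completion branch (`d ≥ deltaD`).
Initial values and clamps (`vh = 10` in [1, 100], `deltaD = 100` in
[1, 10000]) are not published constants; they are configurable defaults
sized so speed has headroom in both directions.

**Scenario 2 (bathtub countdown).** The published rule adapts a single
"countdown" variable, but its timeout branch (add one second, starting from
zero) is only coherent if the adapted quantity is the *allotted* per-round
time rather than the running timer; the state therefore carries both. A
press with time remaining scores +1 and moves the allotted time by −1 s
(floor 5) below threshold or +1 s (cap 15) at/above; a timeout scores −1
and adds +1 s. The published prose for the low-HR press branch says the
countdown "increments"; the printed pseudocode decrements with a floor of
5, and only the decrement is self-consistent with the stated 5 s lower
limit, so the pseudocode is followed. Either terminal event refills the
timer to the adapted allotted time.

**Scenario 3 (falling blocks).** The initial generation quantity is
printed as "0.366 s" (a period) while the adaptation prose says +0.1 makes
blocks *more* frequent (a rate), and the printed bound placement (cap
`5 × 0.366` on the decreasing branch, positivity on the increasing one)
cannot be honored literally under either unit. The default reads
`gen_rate` as a rate in blocks/s with a global clamp [0.1, 1.83]; the
`period` interpretation is kept as an option with reversed signs and the
same numeric bounds applied to the interval in seconds. A caught on-screen
block scores +1 and moves the rate one step toward harder (below
threshold) or easier (at/above); a block that leaves the screen unpressed
scores −1 and leaves the rate alone. Whether scores may go negative is
unstated; they may.

**Test scenario.** The architecture-test rule is simpler by design: every
full 20 s, speed moves ±1 unit on the last reading against 80 bpm, clamped
below at a configurable floor (default 0).

Every step function is pure (frozen dataclasses in, new dataclasses out),
and the CIS (conventional) variant of each controller runs the same timers
and scoring with all difficulty quantities frozen — the proper no-adaptation
control arm for paired comparisons.

## Session model and replay

Events follow the adaptation component's schema: `activityStarted` /
`activityFinished` / `scoreObtained` populate the play history and score
record (a score after an activity that did not finish normally is
discarded, so every stored score is trustworthy); `registerPostAnalytics`
and `executionMovement` are recorded but inert, since the customisations
they served were pruned from the deployed component; `signalActivation`
marks the start of physiological capture. Latest score per scenario is kept.

Telemetry rows are written once per tick with the raw and calibrated HR,
`avgHR`, `w`, scenario id, points, per-scenario cumulative kcal (reset at
each `activityStarted`, matching how cumulative calories are reported per
scenario), and a canonical JSON snapshot of the controller state *plus the
tick's inputs* (press flags, resolved blocks). Floats are serialized with
`repr`, so a written log reads back bit-identically. Because inputs are
recorded, replay needs no random numbers: the engine is re-stepped from the
initial states and every post-tick state must match exactly. The
comparison excludes the configuration-identity fields `mode` and
`interpretation`, so a frozen-difficulty log replays cleanly under either
mode while any behavioural difference still surfaces in the numeric state.

## Simulator

The simulator's job is to close the loop realistically enough to exercise
the engine, not to be a cardiovascular model. Heart rate follows a
first-order relaxation with time constant τ (default 30 s, drawn 25–35 s
per child — a child's on-kinetics are on the order of half a minute)
toward `resting + demand · effort_gain · (hr_max − resting)`, with additive
Gaussian noise (2 bpm·s^½) and clamps [40, hr_max]. `hr_max = 220 − age`.
Cohort children draw age uniformly in [5, 7] years, resting HR in
[70, 90] bpm, `effort_gain` in [0.5, 0.7] (full demand elicits moderate-to-
vigorous exertion, ≈150–170 bpm — children rarely sustain their true
maximum in game play), and press skill in [0.75, 0.95].

Demand is each controller's own difficulty normalised by its clamp range
(speed over [vh_min, vh_max]; `(15 − allotted)/10`; rate over
[floor, cap]), so demand ∈ [0, 1] by construction. Press success follows
`skill · (1 − 0.5 · demand)`, strictly decreasing in difficulty, with an
optional `distraction_p` that randomly abandons attempts (emulating
field-setting adherence problems; off by default). The calorie surrogate is
linear in HR reserve, `max(0, c0 + c1·(hr − resting))` kcal/s with
`c0 = 0.02`, `c1 = 0.0013`: at a moderate ~100 bpm this gives ≈0.04 kcal/s,
i.e. ≈8 kcal per ~200 s scenario segment, the single-digit-kilocalorie
scale such sessions report. The constants are configurable per participant.

A crossover cohort simulates each child in both arms with identical
physiological parameters and independent noise streams (seeds spawned
reproducibly from one master seed). The 10-min rest between arms is not
simulated sample-by-sample; each arm starts from resting HR, which is what
the rest period is for. The 10-min play window is split equally across the
three scenarios (the within-session split is not published; equal thirds
are the neutral choice and configurable). For parameter-recovery
experiments the cohort can be run with both arms frozen and a known
additive offset on one arm's measured HR, making the true arm effect exact
by construction.

What the simulator does *not* emulate: HR drift and fatigue, inter-beat
variability structure, device-specific optical artifacts beyond white
noise, learning effects across rounds, and any code path of the real game.
Passing closed-loop tests therefore show that the *engine* regulates a
plausibly responding player; they are not evidence about real children.

## Statistics

Scenario-level measurements are the per-participant mean HR over a
scenario segment and the final cumulative kcal, named
`Hrate{P1,P2,P3}{UAS,CIS}` and `Gcalorico{1,2,3}{UAS,CIS}`. Descriptives
use n−1 variance and the bias-corrected (sample-adjusted) skewness and
excess-kurtosis estimators, the convention of mainstream statistics
packages — confirmed by the kurtosis standard error, which at n = 29
equals 0.85 under the classical closed form
`2·se_skew·√((n²−1)/((n−3)(n+5)))`, implemented directly since it is not
exposed by scipy. Statistics whose minimum n is not met are reported
absent, never fabricated.

The paired t-test is computed from the differences `d = x_UAS − x_CIS`:
`t = d̄/(s_d/√n)`, `df = n − 1`, two-tailed p from the t distribution, and
the 95% CI `d̄ ± t₀.₉₇₅,df · s_d/√n`. The summary route takes
`(d̄, s_d, n)` directly, so printed report rows can be reproduced without
raw data; the raw route reduces to the summary route, making the two
identical to the last bit. Zero-variance differences with nonzero mean
yield an infinite t, flagged rather than hidden. Reproduction of printed
2-d.p. tables is checked at ±0.02 absolute — the slack print rounding
itself introduces. No multiple-testing correction is applied, matching the
analysis being reproduced; the table renderer notes this. Participants
missing an arm or scenario are excluded with a logged reason (the
exclusion rule behind discarded field records is not published, so
exclusions are explicit and parameterized rather than silent).

## Problem sizes in the shipped checks

The default suite and acceptance script use: exhaustive scenario-2
enumeration (66 transitions) plus 100,000-step random drives for bound
safety; 1,000 random paired datasets for route consistency; 20 simulated
crossover pairs (10-min arms) for closed-loop regulation; and 20 replicated
8-child cohorts for CI coverage of a 5 bpm built-in arm effect, with the
coverage bound set binomially consistent with a nominal ≥90% at 100
replicates. These sizes make the checks statistically meaningful while
keeping a full run in the order of seconds to a minute.
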