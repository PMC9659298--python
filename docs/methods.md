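# Methods

## Model structure

The simulator couples a continuous stock layer to a discrete-event layer on
a daily grid (INITIAL TIME 0, FINAL TIME 720, TIME STEP 1 day; a system
month is 30 days). State consists of three implicit-attitude stocks —
safety capability SCA, safety consciousness SCO, safety motivation SM —
plus memory-phase bookkeeping (intervention count H, days since the last
intervention). Everything else is recomputed each day.

Output equations (structural error terms σ are fixed at 0, reflecting the
insensitivity of feedback-dominated system-dynamics models to non-critical
parameters):

    SB   = SBPV − SBNV
    SBPV = 0.217·SCA + 0.207·SCO + 0.440·SM
    SBNV = 0.012·USPH + 0.086·USPS + 0.038·PWE
    USPH = 0.466·PH + 0.534·PF
    USPS = 0.605·WP + 0.395·LP
    PWE  = 0.527·PW + 0.473·WI

The explicit→SB coefficients are stored signed (negative) in the
coefficient table; SBNV is computed from their magnitudes so the
subtraction in SB applies the negative contribution exactly once. With
PH ≤ 0.5 and the other disturbances ≤ 1, SB is structurally bounded in
[−0.1332, 0.864]; the lower bound uses USPH's ceiling 0.466·0.5 + 0.534 =
0.767.

Intervention increments (one-day duration, absorption G = 0.5 on all four
channels):

    ΔSCA = 0.74·ST          → 0.37 at G = 0.5
    ΔSCO = 0.619·SCL + 0.381·SCU → 0.5
    ΔSM  = 0.128·IM         → 0.064

Both policies fire a pre-entry intervention at t = 0, so these increments
are also the initial stock values.

## Memory dynamics

Between interventions each stock decays by continuous compounding,
`stock ← stock·exp(−rate)` per day, with phase rate

    rate_H = (1/S)·Z^(H−1),   S = 10 days, Z = 0.9,

where H counts fired interventions including the pre-entry one. This decay
law is chosen because 30 days at rate 1/S equal one application of the
forgetting curve exp(−30/S) exactly: the first-phase endpoints follow in
closed form (0.37·e⁻³ ≈ 0.018, 0.5·e⁻³ ≈ 0.025, 0.064·e⁻³ ≈ 0.003), and
phase 2 decays at exactly 90% of phase 1's rate. On an intervention day the
order is decay, then increment, then cap — so each phase's minimum is the
value on the day *before* the intervention.

Z is accepted in (0, 1]: Z = 1 disables the slowing and serves as a control
condition in which every phase decays at the bare rate 1/S.

Complete forgetting: after strictly more than 60 consecutive
intervention-free days the phase count resets to 1, returning the decay
rate to 1/S; stock values are untouched (the mechanism resets the
*attenuation rate*, not the memory content). The next intervention then
advances H to 2 — the model treats one post-reset intervention as restoring
the "second exposure" level of memory strength; nothing in the source
narrative distinguishes this from restarting at H = 1, and the choice only
matters under the passive policy after long gaps. The reset event is logged
on the day it changes the rate, not on every subsequent day the condition
holds.

## Event scheduling

Within a day: E1 draw disturbances → E7 forgetting-reset check → E6 decay →
E2/E4 intervention if due (H += 1, gap counter cleared) → E5 cap at 1 →
output equations. The active schedule is t ∈ {0, 31, 61, …}: the pre-entry
intervention starts a 31-day first phase, after which interventions land on
each month's first day (24 firings in 720 days). The passive trigger is
evaluated on the same month-first grid and fires iff the preceding month's
SB statistic is strictly below 0.2. "Preceding month's SB" defaults to the
SB value on the month's last day (`passive_statistic: last_day`), matching
the narrative convention of checking single-day values at month ends; a
`month_mean` alternative is provided. The threshold comparison is strict,
so SB exactly at 0.2 does not trigger.

Under the active policy the stocks are seed-independent: disturbances feed
SB but never the stocks, and the only SB feedback in the model is the
passive trigger itself. No other feedback is invented.

## Meta-analysis

Per-study correlations are pooled per causal path by fixed-effect
inverse-variance weighting with the large-sample variance
ν = (1 − r²)²/(n − 1). (The source describes the weighting both as
sample-size and as inverse-variance; the printed estimator is
inverse-variance and that is what is implemented — for correlations of
similar magnitude the two differ only in the third decimal.) t- and
F-statistics convert via r = t/√(t² + df) and r = √(F/(F + df)) (numerator
df 1); standardized βs pass through with a warning because no exact
conversion exists (common approximations such as Peterson–Brown's
r ≈ β + 0.05λ are documented here but deliberately not applied silently).
Significance uses Z = |ρ̂|/√var(ρ̂) and the CI is ρ̂ ∓ z_{α/2}·√var(ρ̂) at
α = 0.05 (z_{α/2} = 1.959964, from scipy). Single-study paths are valid and
flagged; a reliability-correction hook r/√(rxx·ryy) exists but is off by
default — the published corrected correlations are consumed as given
inputs, since the per-study reliabilities are not available.

Normalization: a dependent variable with one parent keeps the pooled
estimate; with several parents each coefficient becomes |ρ̂_i|/Σ_j|ρ̂_j|
with its sign re-attached. The packaged coefficient table is the canonical
fixture for the simulator: the normalization rule reproduces its USPH- and
WE-parent rows from the published corrected correlations to three decimals,
while its SCO-parent, USPS-parent and SB-parent rows are not derivable from
any normalization of the published inputs — those rows are therefore
consumed verbatim rather than re-derived, and the normalization operation
is validated only against the arithmetically consistent rows.

The per-study sample sizes inside the packaged effect table are a
reconstruction: only path totals are published, so each path's N is split
as evenly as possible across its k studies (remainder on the last studies).
This affects only meta-analysis examples, never the simulator, which uses
the coefficient fixture directly.

## Synthetic effect tables

`generate_synthetic_effect_table` draws per-study correlations from the
large-sample approximation r ~ N(ρ, (1 − ρ²)²/(n − 1)), clipped into
(−1, 1). It emulates sampling noise around a common population correlation
— exactly the fixed-effect assumption — and deliberately omits what real
coded tables contain: between-study heterogeneity, unreliability
attenuation, selective reporting, and non-normality of r at small n. The
CI-coverage check (95% ± 2.5% over 1000 tables at ρ = 0, k = 50, n = 1000)
therefore validates the estimator's calibration under its own model, not
robustness to heterogeneous literatures.

## Validation surface and known limitations

The anchor values recomputed by `scripts/acceptance.py` are the t = 0
stocks (0.37, 0.5, 0.064, exact closed forms) and the t = 30 first-phase
minima (0.018, 0.025, 0.003 after rounding to the three decimals at which
they are reported). Long-run published trajectory values (stocks at t = 720,
a consciousness cap crossing at the 9th intervention, SB on specific days)
are *not* reproduced: under the literal rate law (1/S)·Z^(H−1) the
consciousness stock first caps near the 16th intervention and the t = 720
stocks land lower than reported, indicating an unrecoverable detail of the
original modelling tool (a different Z application, increment handling or
integrator). The package asserts the qualitative behavior instead:
non-decreasing phase minima, eventual capping, stocks in [0, 1] and SB
within its structural bounds on every day across 100 seeds and both
policies, the closed-form phase recursion to 1e−9 off-cap, and the
active-policy mean final-100-day SB exceeding the passive policy's over 20
seeds.

Problem sizes used by the default validation run: one 721-day trajectory
per check where deterministic, 100 seeds per policy for the bounds sweep,
20 seeds for the policy comparison, 1000 synthetic tables for CI coverage.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; trajectories are byte-identical across reruns of
the same configuration and seed.
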