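# Methods

## The measurement model

A single second-order transient — a one-time polarity flip of all pixels
inside a target shape embedded in a random-dot matrix — produces a percept
with an abrupt onset and a gradual offset. The judgment-of-synchrony task
measures both ends of that percept: the observer adjusts the delay Δt between
the matrix transition (at t_T) and a reference stimulus until the reference
onset appears synchronous with the percept's onset (setting E) or offset
(setting D). Writing e_T for the latency from transition to percept and e_R
for the latency from reference onset to its percept, perceived synchrony on
on-trials means t_T + Δt + e_R = t_T + e_T, so E = e_T − e_R; on off-trials
the percept event additionally includes the persistence duration P, so
D = e_T + P − e_R. The latencies cancel in VP = D − E = P. The package's
tests exercise this cancellation directly (latency invariance) rather than
assuming it.

## Stimulus geometry

The display model is a square matrix (default 600 px subtending 19.15 deg,
0.0319 deg/px). Masks are rasterized on pixel centers with a half-open radial
interval [r, R), so nested shapes partition pixels without double counting.
Coordinates are 0-based with the matrix center at ((N−1)/2, (N−1)/2).

The printed annulus numbers (outer diameters 100/200 px, "thickness"
25/75 px) are mutually impossible as diameter plus ring width (a 100-px
annulus cannot carry a 75-px ring). The default `DIAMETER_DIFF` convention
reads thickness as outer-minus-inner *diameter* (ring width = thickness/2):
it is the only reading under which all four annuli fit a central
300 × 300 px region *and* the small/thick annulus equals the large/thin one
in area (π·t·(2R−t) with t the half-thickness: 12.5·187.5 = 37.5·62.5). The
`RADIUS_WIDTH` alternative (sizes as outer radii, thickness as ring width) is
also equal-area and is exposed as a config option; the naive
`DIAMETER_WIDTH` reading exists only to fail loudly. The printed degree
equivalent "2.89 deg" for 75 px is inconsistent with the stated display scale
(75 px = 2.39 deg); pixel values are treated as ground truth throughout.

Filling-in features: for a disk the edge signal lives on the circumference
(C = 2πR) and the spread travels the radius (D_fill = R); for an annulus both
edges contribute (C = 2π(R+r)) and the travel distance is the ring width
(D_fill = R − r). A config flag substitutes the printed thickness number for
the derived ring width, since which of the two entered the original
regression is not recoverable; the default is the physical ring width.

The largest disk (6 deg) at the largest eccentricity (7.5 deg) extends 
beyond the matrix half-width (9.575 deg). Rasterization therefore raises by
default and clips only on request; the simulation and analysis never
rasterize, so the pipeline is unaffected.

## The decay trace and its calibration

The persistence trace is the impulse response of three cascaded leaky
integrators with distinct rates a, b, c (s⁻¹):

    f(t) = D·[(c−b)e^(−at) + (b−a)e^(−ct) − (c−a)e^(−bt)],

the hypoexponential density up to scale, hence non-negative, zero at t = 0,
single-peaked, and asymptotically zero. D is fixed by peak normalization
(max f = 1). The closed form is antisymmetric under reordering the rates;
normalization uses the signed extremum of |f|, so the normalized curve is
invariant under b ↔ c.

No units are stated for the rates; a = 50 is read as 50 s⁻¹ (a 20 ms time
constant, plausible for an early visual stage). The percept's offset is
defined as the first time the normalized trace falls through a threshold.
The threshold is 0.01: a literal zero is never reached at finite time (the
tail is a positive sum of decaying exponentials), so the solver rejects it.

One constraint — f(t_off) = 0.01 at a target offset time — cannot determine
both free rates, so c is tied to b by a fixed ratio (default c/b = 1.2,
configurable) and b is found by root bracketing on the crossing time: the
peak is located by a 1 ms grid scan refined by bounded minimization
(xatol 1e−12), the crossing by expanding march plus Brent's method
(xtol 1e−12). Because the crossing time is monotone in b only between the
degenerate coincidences b = a and c = a, the search runs over the segments
around those points; the shortest target (200 ms) indeed lands at
b ≈ 44.5 s⁻¹ > a/1.2. One numerical caveat: across the calibrated family,
tail values are totally ordered in the target time only once every curve has
peaked (the longer-target curves peak later and are still rising while the
shortest has peaked); the ordering test starts there.

## The synthetic observer

The observer is the package's data generator; it is parametric, not a
cognitive theory. Per repetition of the stimulus sequence it perceives the
asynchrony A = (t_T + Δt + e_R) − perceived event time, corrupted by Gaussian
judgment noise (resampled every repetition). With keys, it applies the step
in {−100, −10, +10, +100} ms that most reduces |A| and confirms when |A| is
below the confirmation JND (default 20 ms) *and* no step would improve it —
the second clause keeps a noiseless observer from settling up to a full JND
away and makes the recovery error at most half the smallest step per setting.
With the knob it sets Δt ← Δt − A (presented value rounded to the 10 ms
frame, continuous value retained) and confirms once |A| is within a display
frame. Trials run at least two repetitions; trials exceeding
`max_repetitions` (default 200) are kept and flagged non-converged. The
semi-adaptive initializer starts each first encounter of a (condition, task)
at a ±30 ms jitter around zero and later trials at the running mean of prior
estimates plus jitter, exactly as in the adjustment procedure it emulates;
the proxy experiment instead starts uniformly within ±200 ms of the physical
event.

Condition effects enter through the persistence duration. For transient
shapes, a subject's persistence is a base duration (drawn per subject) plus
additive per-condition shifts; for the proxy stimulus, the offset percept is
read directly off the *physical* decay trace at the observer's criterion, so
a criterion of 0.01 tracks the calibrated offset time with unit slope by
construction — deviations from unit slope in the simulation come only from
noise and the adjustment dynamics.

The reference-modality effect is modelled as a modality-specific persistence
shift, not an e_R difference: by the cancellation argument above, an e_R
shift moves E and D equally and cannot change VP (and would change E, which
the measured pattern contradicts). A per-modality e_R remains available in
the profile for exploring latency effects.

Observer-panel defaults (the study conditions the generator emulates):

| parameter | Exp 1 (annuli) | Exp 2 (proxy) | Exp 3 (disks) |
|---|---|---|---|
| subjects | 9 | 4 | 9 |
| reps per cell/task | 20 | 10 | 10 |
| device | keys | knob | knob |
| base persistence (ms) | N(489.7, 150) | trace @ 0.01 | N(1007.95, 250) |
| condition shifts (ms) | thickness ±34.5, size ±27.8, modality ±51.1 | — | +67.78 per deg of diameter |
| judgment noise SD (ms) | 30 | 70 | 80 |
| offset-criterion jitter SD (ms) | 35 | 60 | 200 |
| e_T / e_R (ms) | N(60,15) / N(40,15) aud, N(50,15) vis | same | same |

Condition means (grand means, marginal effects, the size slope) are the
reported study-level values; dispersion parameters (between-subject SD,
judgment noise, jitter) are not reported at that granularity and were chosen
once as field-plausible magnitudes: noise SDs sit near the reported
repetition SDs for each device (keys ≈ 30 ms, knob ≈ 70–170 ms), and the
offset-criterion jitter makes offset settings roughly twice as variable as
onset settings, the qualitative asymmetry the adjustment data show. The
jitter applies only to off-trials, reflecting that the offset of a gradually
fading percept is intrinsically the vaguer event.

What the generator does *not* emulate: eye movements aborting percepts,
learning or fatigue across sessions, lapses, any dependence of judgment noise
on Δt, or a mechanistic link from stimulus geometry to persistence (condition
effects are injected additively). Passing recovery tests therefore shows the
*pipeline* is unbiased and latency-free under the stated observer model, not
that the model captures human adjustment behaviour.

## Statistics

`rm_anova` is a fully-within factorial decomposition: each effect's SS comes
from inclusion–exclusion-centered cell means and is tested against its own
subject × effect interaction. Greenhouse–Geisser epsilon is computed from the
covariance of orthonormalized effect contrasts (Kronecker products across the
effect's factors), clipped to [1/df, 1]; Mauchly's test uses the same
covariance (it requires more subjects than contrast dimensions; when it is
unavailable the corrected p is used, conservatively). Following the original
analysis convention, the corrected p is adopted only when sphericity is
rejected at α = 0.05, and no multiple-testing correction is applied anywhere.
pingouin and statsmodels implement overlapping special cases and serve as
independent oracles in the tests; they are not used in the pipeline because
neither covers three-factor within designs with GG correction.

Within-subject CIs follow Loftus–Masson: half-width =
t_{(n−1)(k−1)} · √(MS_{subject×condition}/n) over the full condition
crossing. The drift QC operationalizes the exclusion of a subject whose
offset settings rose monotonically through the session: Spearman ρ between
offset Δt and trial order, flagging ρ > 0.5 with p < 0.05 (the thresholds are
this package's operationalization of an informal rule, and are parameters).

The filling-in regression VP = b0 + b1·C + b2·D is ordinary least squares on
per-condition VP means with features in pixels; which cells enter (collapsed
over modality by default) is configurable because the original cell means are
not recoverable. Cross-prediction applies the annulus-fit coefficients to
disk features and reports the Pearson correlation with observed disk means.
The speed conversion divides 1000 ms by twice the VP-vs-diameter slope, since
the filled-in distance is the radius.

## Problem sizes and determinism

All randomness flows from seeded numpy generators; `simulate_experiment`
spawns one child stream per subject, so runs are reproducible from a single
seed and a profile list. The test suite simulates full-size designs (9 × 320
trials for the annulus design) — the adjustment loop is cheap — and the
decay calibrations are cached per parameter set. Default test and acceptance
runs complete in well under a minute on one core.
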