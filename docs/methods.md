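# Methods

## Model

Muscle coordination over one cutting cycle is modelled as a non-negative
mixture: the envelope matrix `X` (M = 16 muscles × K = 200 cycle points)
is approximated by `S · P`, with `S ≥ 0` the muscle-weighting matrix (one
column per motor module) and `P ≥ 0` the activation signals. The model
assumes (i) envelopes are non-negative and amplitude-normalized to [0, 1],
(ii) a module's muscle balance is fixed within a condition while its
recruitment varies in time, and (iii) trial-to-trial variation is additive
noise on the envelope. Nothing in the fit enforces physiological
interpretability; modules are a low-rank description of the data.

### Fitting

The Frobenius objective `‖X − S·P‖²` is minimized by the classical
multiplicative updates

    P ← P ⊙ (SᵀX) ⊘ (SᵀS P + ε),    S ← S ⊙ (X Pᵀ) ⊘ (S P Pᵀ + ε)

with ε = 1e−12 guarding the denominators. The updates preserve
non-negativity and never increase the error (asserted per iteration when
`track_error` is on). The objective is non-convex, so each fit runs
`n_restarts` independent uniform-(0,1] initializations scaled by
`sqrt(mean(X)/N)` and keeps the lowest-error restart. Default stopping:
relative error change < 1e−6 or 1000 sweeps. Fitted sets are
canonicalized — weighting columns scaled to unit Euclidean norm with the
scale absorbed into the matching activation row (this leaves `S·P`
bit-identical) — and ordered by activation peak time.

### Reconstruction quality and dimensionality

`VAF = 1 − SSE/SST` with **uncentered** SST (`ΣX²`), the prevailing
convention for synergy analyses; it makes the zero reconstruction score 0.
A centered variant sits behind `centered=True`. The VAF-vs-N curve uses,
besides the random restarts at each N, a warm start built from the
previous N's solution plus one random module — the multiplicative updates
cannot worsen that candidate, so the curve is non-decreasing by
construction. Dimensionality selection takes the smallest N with
`VAF ≥ 0.80` whose marginal gain to N+1 is below `gain_eps = 3` percentage
points. The 3-point default places a typical "one more module adds ~4 %"
situation just on the rejecting side of the boundary; both knobs are
arguments. If the last curve point is the first to clear the floor it is
accepted when the incoming slope is already flat; a curve that never
reaches the floor raises.

### Cross-condition comparison

Similarity is the normalized scalar product (cosine) between weighting
columns or activation rows, with r > 0.80 flagged "similar". Two sets are
matched by linear-sum assignment maximizing total similarity; greedy
matching exists for comparison but assignment is the default because
greedy can mismatch near-duplicate modules. Activation signals extracted
from concatenations of different trial counts are first folded to a
per-cycle mean (`cycle_average`) so they compare on the shared 200-point
cycle; no time warping is applied.

The fixed-factor cross-reconstruction holds one factor fixed (e.g.
unperturbed weightings), draws the free factor uniformly at random
(seeded), and applies exactly 1000 multiplicative updates to the free
factor only. Baselines replace the fixed factor with a uniform random
matrix of the same shape. `iterations=0` reports the VAF of the random
initialization as a null reference. The fixed matrix is verified untouched
after the fit.

## Signal processing

Fixed order: band-pass → segment → rectify + low-pass → time-normalize →
amplitude-normalize. All filters are second-order zero-phase Butterworth
(`sosfiltfilt`, even-reflection padding of 12 filter orders); the envelope
low-pass is 10 Hz, the band-pass 20–500 Hz at a 2048 Hz sampling rate. The
filter order of the envelope stage is not uniquely dictated by convention;
second-order zero-phase is used for both stages and recorded in the
configuration. Residual undershoot after low-passing is clipped at zero
(NMF needs non-negative input); the clipped L1 mass is logged in
`meta['clip_l1']`. Time normalization linearly interpolates each channel
onto 200 equally spaced points spanning contralateral initial contact to
ipsilateral toe-off. Two amplitude normalizations exist because they feed
different analyses: whole-cycle pooled per-muscle peak (for NMF, values in
[0, 1]) and stance-period pooled peak (for epoch amplitudes and CCR/CCI,
where swing samples may exceed 1).

## Kinetics

Initial contact is the first sample with vertical force above 20 N
sustained for a 5 ms debounce window; toe-off is the first subsequent
sample at or below threshold sustained equally long (end of trace if the
recording stops while loaded). CoM power is `F·v/m` in W per kg of body
mass; the bracketed per-body-weight variant (÷ m·g) is available via
`per="weight"`, but W·kg⁻¹ is the default unit. Load acceptance is the
contiguous negative-power span after contact and propulsion the positive
span that follows; with noisy multi-crossing traces the longest negative
span before the longest positive span is used and a warning emitted.
External work is the trapezoidal integral of power over each phase, so
`w_lac ≤ 0 ≤ w_prp` holds by construction. Approach speed is the mean CoM
velocity magnitude 200–100 ms before contact, with velocity from
second-order central differences of 10 Hz low-passed position. Horizontal
force peaks are |Fy|/m and |Fx|/m maxima over the first half of stance;
absolute values are used because the peak's direction convention differs
between force-plate setups.

## Co-contraction

Epochs: PRE = 10 ms before initial contact; LA = contact to the negative
CoM-power peak; PRP = a 50 ms window centered (±25 ms) on the positive
power peak. Epoch amplitudes are arithmetic means of the stance-normalized
envelopes. CCR = mean(BF, ST)/mean(VM, VL, RF). The CCI definition
"averaged activation of all knee flexors and extensors times CCR" is
implemented as the grand mean of the five muscles × CCR (so CCI is
homogeneous of degree 1 under common scaling while CCR is invariant); a
sum-based variant is available via `mode="sum"` since the wording admits
both readings.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the physiology that produces it. Study conditions (defaults): 16 muscles,
5 modules, 200-point cycles, 10 unperturbed trials plus 1 perturbed trial
per subject, envelope noise std = 5 % of the clean-mixture RMS. Activation
signals are Gaussian bumps in cycle-percent space (std 8 %) peaking at
10/37/64/83/95 % — unimodal, cycle-locked recruitment matching the five
functional modules of cutting (pre-contact quadriceps/dorsiflexor,
load-acceptance hamstrings/gluteals, calf propulsion, trunk control, swing
preparation). The structured preset gives each module dominant weights
(uniform 0.6–1.0) on its muscle group and small background weights
(0–0.12) elsewhere; the generic generator draws fully random sparse
weightings. Ipsilateral contact sits at 30 % of the cycle, so the
hamstring module's 37 % peak falls inside load acceptance. The perturbed
condition multiplies that module's activation by 0.5 from contact to 62 %
of the cycle — a 150 ms support-surface translation occupying load
acceptance — leaving weightings untouched, which is exactly the asymmetry
the cross-reconstruction is designed to detect.

Noise is additive Gaussian clipped at zero: envelopes are non-negative and
no deeper generative claim is intended. Clipping removes noise mass where
the clean envelope is near zero, so the requested noise std is only
reached away from the floor; tests assert the std on samples where the
clean signal exceeds 3σ and bound the global std from above. Inter-trial
variability beyond envelope noise (the `gain_jitter` option, per-module
recruitment-gain jitter) defaults to off, as real-data variability of this
task is not characterized; passing tests therefore demonstrate correctness
of the machinery under the stated noise model, not robustness to every
real-world artifact (electrode lift, crosstalk, fatigue drift,
inter-subject timing differences are all absent).

Kinetic traces: vertical force follows a `sqrt(sin)` stance profile
(chosen so the 20 N threshold is crossed within one sample of the planted
contact at realistic peak forces), horizontal forces are single bumps in
the first half of stance (peaks 10 and 3.5 N/kg), and the CoM velocity is
constructed along the instantaneous force direction to realize a
single-sign-change `−sin(2πs)` power profile (amplitude 15 W/kg). A 150 ms
pre-cycle lead precedes the cycle so the approach-speed window fits in the
recording; before contact the CoM moves at the nominal approach speed
(default 2.67 m/s).

## Identifiability remark

Exact recovery of planted factors by NMF requires the factorization to be
essentially unique. The structured preset is deliberately *not* fully
identifiable: background weights and the overlapping 83 %/95 % activation
bumps admit alternative factorizations with equal reconstruction error, so
matched weighting similarity to truth plateaus around 0.996–0.999 rather
than 1. Recovery-oracle tests that demand ≥ 0.999 similarity therefore use
a sparse, well-separated configuration; the preset conditions are held to
the ≥ 0.95 mean-similarity requirement.

## Problem sizes and numerical choices

The test suite and acceptance script run reduced fit budgets (2 restarts,
250–300 sweeps, tol 1e−5) and 20–50 seed replicates; these sizes give
stable pass/fail behaviour for every property checked while keeping runs
interactive. Public API defaults are stricter (20 restarts, 1000 sweeps,
tol 1e−6). Ties in activation peak timing (constant rows) return the
earliest index with a warning. All stochastic operations take explicit
seeds; per-restart and per-N seeds are spawned from a master generator so
results are reproducible bit-for-bit.

## Known limitations

* Joint angles/moments are consumed as precomputed series; no inverse
  dynamics or marker processing.
* Statistical inference across subjects is limited to descriptive
  medians/quartiles — cohort t-tests require real cohort data.
* Only C3D-free text formats are supported (EMG CSV, kinetics TSV, JSON
  sidecars).
* The synthetic perturbation rescales activation signals only; condition
  effects that genuinely reorganize muscle weightings are out of the
  generator's vocabulary and would need a different ground truth.
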