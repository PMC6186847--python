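# Methods

## Model

A real signal narrow-bandpassed around center frequency `fc` (sampling rate
`fs`, ω₀ = 2π·fc/fs rad/sample) has analytic form
`x̂_t = A_t e^{i(ω₀ t + θ_t)} + Ŵ_t` with envelope `A_t` and residual phase
`θ_t` varying slowly relative to ω₀.  The ratio of successive clean samples
is then ≈ `e^{iω₀}`, which motivates the state-space model

    ŝ_{t+1} = e^{iω₀} ŝ_t + η̂_t,   η̂_t ~ CN(0, σ)
    x̂_t     = ŝ_t + Ŵ_t,           Ŵ_t ~ CN(0, α)

`CN(0, v)` is the circular complex Gaussian whose real and imaginary
components each have variance `v` (covariance `v·I` in the equivalent 2-D
real form, whose transition matrix is the rotation by ω₀).  The residual
`r(t) = p(t) − ω₀ t` of the unwrapped phase `p` is the series of interest:
flat for a stationary band, stepped at genuine phase resets, and violently
jittery wherever the envelope approaches zero (the arctangent that defines
the phase is ill-conditioned there — the *spurious phase variations* this
package removes).

## Smoother

Because every covariance in the model is isotropic, the Kalman filter and
the fixed-interval (RTS) smoother reduce *exactly* to scalar variance
recursions with complex means:

* forward: `p′ = p_t + σ`, gain `K_t = p′/(p′+α)`,
  `μ_{t+1} = Bμ_t + K_t(x̂_{t+1} − Bμ_t)`, `p_{t+1} = p′α/(p′+α)`;
* backward: `g_t = p_t/(p_t+σ)`, `μ̄_t = μ_t + g_t(Bᵀμ̄_{t+1} − μ_t)`,
  `p̄_t = p_t + g_t²(p̄_{t+1} − p_t − σ)`.

The scalar filtered variance converges to the Riccati fixed point
`p* = (−σ + √(σ² + 4σα))/2`; both passes are verified against an
independently written full-matrix Kalman filter/RTS smoother to 1e-10.
The effective two-sided averaging half-width of the smoother is ≈ 1/K*
samples with `K* = (p*+σ)/(p*+σ+α) ≈ √(σ/α)` for σ ≪ α; spurious
excursions shorter than this window are suppressed, while sustained mean
changes (genuine resets) pass through at full amplitude.

Numerical conventions: the innovation uses the next observation
`x̂_{t+1}` (standard predict–update ordering).  Initialization is
data-anchored and diffuse: `μ₁` = first observation, `p₁ = 10(α+σ)`
(falling back to 1 when α = σ = 0), so the prior is forgotten within a few
steps.  Degenerate limits are closed-form: a vanishing innovation variance
gives gain 1, a vanishing `p_t + σ` gives smoother gain 0, so with
σ = α = 0 the smoother is the identity on an exact rotation.  An explicit
`p1 = 0` together with α = σ = 0 is rejected.

## Parameter estimation

* **α (measurement noise).**  The signal is band-passed by an ensemble of
  M = 100 zero-phase (forward–backward `sosfiltfilt`) IIR elliptic filters —
  order 6, 50 dB stop-band attenuation, 0.01 dB pass-band ripple, 0.5 Hz
  default pass-band — whose center frequencies are independently perturbed
  by a relative amount uniform in ±1% (seeded, bit-reproducible).  α̂ is the
  per-sample cross-member variance of the analytic members, averaged over
  samples and the two components.  This has the signal's units squared, as
  the observation equation requires; a literal phase-variance mode
  (radians²) is available behind `estimate_alpha(..., mode="phase")` for
  comparison.
* **σ (process noise).**  With `d_t = x̂_{t+1} − e^{iω₀} x̂_t`,
  ε = per-component var(d) equals σ + 2α when Ŵ is white, so σ is
  admissible in [max(ε − 2α, 0), ε].  The working value is σ = β·ε clipped
  to [0, ε], with β the single user knob (default 0.5).  β = 0 deliberately
  selects σ = 0 — maximal smoothing, collapsing the instantaneous frequency
  to a constant — rather than the lower end of the admissible interval,
  which would forbid that limit.  Note that after narrow-band filtering the
  measurement noise is *not* white (d_t largely cancels it), so on filtered
  data ε understates σ + 2α; this bias is harmless here because β, not the
  moment identity, sets the operating point, and the identity itself is
  verified on data simulated from the exact model.
* **Transients.**  The first and last `ceil(3·fs/bandwidth)` samples are
  flagged (not deleted) in a companion mask, a conservative multiple of the
  ~1/bandwidth settling time of the narrow filter.

## Synthetic generators

* **AM tone** — envelope `cos²(ω₀ᵉⁿᵛ t) + ε` (floor ε, default 0.05) on a
  carrier, with a cumulative π added to the carrier phase after each listed
  shift time.  Envelope dips plus noise produce spurious excursions;
  the π shifts are labeled genuine resets.
* **Random-shift sinusoid** — constant-amplitude sinusoid (default 7.4 Hz at
  250 Hz) with n cumulative jumps of magnitude uniform in [π/8, 7π/8],
  random sign, at uniform interior indices with ≥ 25-sample gaps and a
  150-sample edge margin (so the 10-sample matching tolerance is well-posed
  and edge transients do not overlap labels).
* **EEG-like mixture** — sinusoids at {2, 5, 7.6, 12, 20} Hz with
  amplitudes {1, 0.8, 1, 0.5, 0.3} plus white Gaussian noise rescaled so the
  realized var(clean)/var(noise) equals the target SNR exactly.

What these emulate — and what they do not: the mixtures reproduce the
band-power layout and the low-envelope phenomenology of ongoing EEG but use
white (not 1/f) noise, stationary amplitudes and no artifacts.  Passing
tests therefore demonstrate the estimator's behavior under the stated model
and its robustness to severe stationary noise, not performance on recorded
EEG with nonstationary, colored noise.

## Change-point evaluation

Detection runs on the phase residual with binary segmentation over segment
means.  A split must reduce the within-segment squared error by more than an
**absolute** penalty (default 10 rad²·samples ≈ a π/8 step sustained for
~130 samples).  The penalty is deliberately not adapted to each series'
noise level: the pre- and post-smoothing residuals are compared on the same
physical phase scale, so "how many sizeable mean shifts does this residual
contain" is answered identically in both conditions.  Narrow-band filtering
(and smoothing) smears a step into a symmetric ramp, so each accepted split
is re-localized by a local two-mean fit (window ±60 samples, clipped at
midpoints to neighboring splits), and adjacent splits bracketing one
monotone transition closer than 60 samples are merged to the ramp center.
The greedy detector agrees with exhaustive least-squares segmentation on
≥ 95% of random ≤ 2-step series.

Scoring: greedy nearest-first one-to-one matching within 10 samples;
unmatched detections are FP, unmatched truths FN.  MCC needs true
negatives, which event detection does not define; every sample is treated
as a candidate event, `TN = N − TP − FP − FN`.  This choice inflates TN and
hence MCC magnitudes, but affects neither sign nor the pre/post ordering.
Zero denominators give MCC = 0.

The benchmark grid defaults to n ∈ {1..4} shifts × SNR ∈
{0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 1.0, 2.0} (log-ish spacing concentrated
in the high-noise regime the method targets) × 200 batches per cell on
1500-sample records; the full-scale protocol uses 2000 batches.  Within the
benchmark the generator retains the noiseless signal, so the smoother runs
with "oracle" parameters — α from the band-passed noise component, σ from
the differenced clean band-passed analytic signal — the configuration in
which the true signal is known; the ensemble pipeline is the route for real
recordings.  The benchmark band-pass uses a 4 Hz width: the 0.5 Hz default
is appropriate for 60 s recordings but its ~2 s settling time would consume
most of a 6 s record.

## Known limitations

* α is constant over the record; bursty or nonstationary noise is averaged.
* Strong smoothing (small β) widens genuine reset transitions by ≈ 1/K*
  samples and can merge resets closer than that; the benchmark's FN
  increase after smoothing is exactly this cost.
* The moment identity ε = σ + 2α assumes white measurement noise and is
  biased low on narrow-band-filtered data (see above).
* The smoothed posterior variance p̄_t is data-independent (constant α), so
  it cannot itself flag which excursions were removed; the cross-ensemble
  spread of smoothed phases serves that diagnostic role.
* Detection assumes piecewise-constant residual means; slow drifts
  (frequency mismatch between signal and analysis band) appear as ramps and
  can be over-segmented in either condition.
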