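# phasesmooth

Removal of **spurious phase variations** from narrow-bandpassed oscillatory
signals with a complex linear-Gaussian Kalman smoother.

## The problem

Phase-synchronization analyses of EEG and other neural oscillations start
from the instantaneous phase (IP) of a narrow-bandpassed signal, obtained
from the analytic signal `x̂(t) = x(t) + iH(x(t))` as `θ(t) = atan2(H(x), x)`,
with instantaneous envelope (IE) `A(t) = |x̂(t)|`.  Whenever the envelope
approaches zero, both arguments of the arctangent are small and noise
dominates: the phase exhibits large, abrupt excursions that look exactly
like the stimulus-induced phase resets one is trying to detect, but carry no
physiological meaning.  These artifacts distort phase-locking and
synchronization measures.

## The method

`phasesmooth` models the clean analytic signal of a band centered at
`fc` (ω₀ = 2π·fc/fs rad/sample) as a slowly modulated rotation:

    ŝ_{t+1} = e^{iω₀} ŝ_t + η̂_t,   η̂_t ~ CN(0, σ)
    x̂_t     = ŝ_t + Ŵ_t,           Ŵ_t ~ CN(0, α)

Splitting real and imaginary parts gives a 2-D real linear-Gaussian state
space whose transition is the rotation by ω₀ and whose covariances are all
isotropic, so the Kalman filter and fixed-interval smoother reduce to scalar
variance recursions (implemented exactly, and verified against a full-matrix
filter/smoother to 1e-10).  Where the envelope is large the observations are
trusted; where it collapses, the smoother interpolates the rotation through
the gap — removing the spurious excursion while sustained, genuine phase
resets survive.

Parameters are estimated from the data:

* **α** — cross-member variance of an ensemble of M = 100 zero-phase
  elliptic band-pass filters with slightly perturbed center frequencies;
* **σ** — from ε = var(x̂_{t+1} − e^{iω₀} x̂_t) (which equals σ + 2α for
  white measurement noise), admissible in [max(ε − 2α, 0), ε], with a single
  user knob β selecting σ = β·ε.  β = 0 removes all phase variation
  (constant instantaneous frequency); large β reproduces the raw phase.

An evaluation suite detects mean shifts in the phase residual
`r(t) = p(t) − ω₀t` (binary segmentation, verified against exhaustive
segmentation), matches them to ground truth within 10 samples, and scores
TP/FP/FN and the Matthews correlation coefficient (MCC).

## Worked example

`examples/02_remove_spurious_jitter.py` builds an amplitude-modulated 10 Hz
tone whose envelope dips to 0.05 twice per second, with a genuine π shift at
t = 2 s and additive noise, then smooths its phase:

```
alpha (measurement noise)  : 4.21e-03
sigma (process noise)      : 8.20e-07
residual step at the reset : pre 2.96 rad -> post 2.98 rad
low-envelope excursion     : pre 1.15 rad -> post 0.06 rad
```

The genuine reset (≈ π) is untouched while the noise-driven excursion inside
the envelope dip shrinks by ~95%.  The other examples cover the basic phase
decomposition (`01`), data-driven parameter estimation with the filter
ensemble (`03`), and a small pre- vs post-smoothing detection benchmark
(`04`), where smoothing cuts mean false positives at SNR 0.05 from ~9.9 to
~2.9 per 1500-sample record and raises the MCC.

A thin CLI wraps the same functionality:

```bash
phasesmooth simulate shifts --seed 3 --fs 250 --fc 7.4 --out signal.csv
phasesmooth smooth signal.csv --fc 7.4 --beta 0.005 --out run
phasesmooth evaluate signal.csv --fc 7.4 --out report.json
```

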