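"""Remove a low-envelope phase excursion while keeping a genuine pi reset.

Generates an amplitude-modulated 10 Hz tone whose envelope periodically
dips to 0.05, adds noise, and applies the Kalman smoother.  At the envelope
dips the measured phase is dominated by noise (spurious excursions); the
genuine pi shift at t = 2 s is a sustained change the smoother preserves.
"""

import numpy as np

import phasesmooth as ps

fs = 250.0
spec = ps.AMSignalSpec(
    omega0_env=2 * np.pi * 0.5, omega1=2 * np.pi * 10.0, epsilon=0.05,
    shift_times=(2.0,), fs=fs, duration=4.0, noise_sd=0.3, seed=7,
)
lab = ps.generate_am(spec)

fspec = ps.FilterSpec(fc=10.0, bandwidth=6.0, M=1, perturbation_scale=0.0)
obs = ps.bandpass_analytic(lab.signal, fspec)
pre = ps.decompose(obs, 10.0)

# measurement noise from the known noise part; process noise via beta
noise_a = ps.bandpass_analytic(ps.RealSignal(lab.noise, fs=fs), fspec)
alpha = 0.5 * (noise_a.samples.real.var() + noise_a.samples.imag.var())
om = 2 * np.pi * 10.0 / fs
sigma = ps.estimate_sigma(obs, om, alpha, beta=0.005).sigma_point
post = ps.backward_pass(
    ps.forward_pass(obs, ps.KalmanParams(omega0=om, sigma=sigma, alpha=alpha))
).smoothed_phase

u = int(lab.true_change_indices[0])
step = lambda d: abs(np.mean(d.residual[u + 30 : u + 90]) - np.mean(d.residual[u - 90 : u - 30]))
dip, quiet = slice(340, 411), slice(150, 300)
exc = lambda d: np.max(np.abs(d.residual[dip] - np.median(d.residual[quiet])))

print(f"alpha (measurement noise)  : {alpha:.2e}")
print(f"sigma (process noise)      : {sigma:.2e}")
print(f"residual step at the reset : pre {step(pre):.2f} rad -> post {step(post):.2f} rad")
print(f"low-envelope excursion     : pre {exc(pre):.2f} rad -> post {exc(post):.2f} rad")
print()
print("Smoothing keeps the ~pi step (a genuine reset) but removes most of the")
print("excursion inside the envelope dip, where the phase is noise-driven.")
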