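"""Synthetic oscillatory test signals with labeled phase resets.

Three generators cover the evaluation protocol:

* :func:`generate_am` — an amplitude-modulated tone whose envelope
  ``cos(omega0_env * t)^2 + epsilon`` periodically dips to the floor
  ``epsilon``, with the carrier phase shifted by pi at listed change times.
  The envelope dips produce *spurious* phase excursions under noise; the
  pi shifts are *genuine* phase resets.
* :func:`generate_random_shifts` — a constant-amplitude sinusoid with n
  cumulative phase jumps of magnitude uniform in [pi/8, 7pi/8] (random sign)
  at random, well-separated sample indices; the benchmark workhorse.
* :func:`generate_synthetic_eeg` — an EEG-like superposition of sinusoids
  plus white Gaussian noise scaled to an exact target SNR
  (``var(clean) / var(noise)``).

All generators are deterministic given their seed and return a
:class:`LabeledSignal` carrying the noisy signal, the noiseless signal and
the ground-truth change indices for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analytic import RealSignal

__all__ = [
    "AMSignalSpec",
    "RandomShiftSpec",
    "SyntheticEEGSpec",
    "LabeledSignal",
    "generate_am",
    "generate_random_shifts",
    "generate_synthetic_eeg",
    "DEFAULT_EEG_COMPONENTS",
]

#: Default EEG-like component table: (frequency Hz, amplitude, phase offset rad).
#: Delta/theta/alpha/beta-band sinusoids with decreasing amplitude at higher
#: frequency; the 7.6 Hz alpha component is the analysis target.
DEFAULT_EEG_COMPONENTS: Tuple[Tuple[float, float, float], ...] = (
    (2.0, 1.0, 0.0),
    (5.0, 0.8, 0.0),
    (7.6, 1.0, 0.0),
    (12.0, 0.5, 0.0),
    (20.0, 0.3, 0.0),
)


@dataclass(frozen=True)
class LabeledSignal:
    """A noisy signal plus its noiseless version and ground-truth resets."""

    signal: RealSignal
    true_change_indices: np.ndarray
    clean_signal: RealSignal

    def __post_init__(self):
        idx = np.asarray(self.true_change_indices, dtype=int)
        object.__setattr__(self, "true_change_indices", idx)
        n = len(self.signal)
        if idx.size:
            if np.any(np.diff(idx) <= 0):
                raise ValueError("change indices must be sorted and unique")
            if idx.min() < 0 or idx.max() >= n:
                raise ValueError("change indices out of range")

    @property
    def noise(self) -> np.ndarray:
        return self.signal.samples - self.clean_signal.samples


@dataclass(frozen=True)
class AMSignalSpec:
    """Amplitude-modulated tone with pi phase shifts.

    ``omega0_env`` (rad/s) modulates the envelope ``cos(omega0_env t)^2 +
    epsilon``; ``omega1`` (rad/s) is the carrier.  After each time in
    ``shift_times`` (seconds) a further pi is added to the carrier phase.
    """

    omega0_env: float
    omega1: float
    epsilon: float
    shift_times: Tuple[float, ...]
    fs: float
    duration: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shift_times", tuple(float(u) for u in self.shift_times))
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        nyq = np.pi * self.fs  # rad/s
        if max(abs(self.omega1), abs(self.omega0_env)) >= nyq:
            raise ValueError("component frequencies must be below Nyquist")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(set(self.shift_times)) != len(self.shift_times):
            raise ValueError("duplicate shift times")
        for u in self.shift_times:
            if not (0 < u < self.duration):
                raise ValueError(f"shift time {u} outside (0, {self.duration})")


def generate_am(spec: AMSignalSpec) -> LabeledSignal:
    """Generate the amplitude-modulated tone with cumulative pi shifts."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    indices = np.sort(np.array([int(round(u * spec.fs)) for u in spec.shift_times], dtype=int))
    if indices.size and np.any(np.diff(indices) == 0):
        raise ValueError("shift times collapse onto the same sample; increase their spacing")
    offset = np.zeros(n)
    for k in indices:
        offset[k:] += np.pi
    envelope = np.cos(spec.omega0_env * t) ** 2 + spec.epsilon
    clean = envelope * np.cos(spec.omega1 * t + offset)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + (rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0)
    return LabeledSignal(
        signal=RealSignal(noisy, fs=spec.fs),
        true_change_indices=indices,
        clean_signal=RealSignal(clean, fs=spec.fs),
    )


@dataclass(frozen=True)
class RandomShiftSpec:
    """Sinusoid with n random cumulative phase jumps.

    Jump magnitudes are uniform in ``shift_magnitude_range`` (default
    [pi/8, 7pi/8]) with random sign; jump locations are uniform over the
    record interior (at least ``edge_margin`` samples from either end) with
    pairwise gaps of at least ``min_gap`` samples, so the 10-sample matching
    tolerance of the scorer cannot make two true shifts ambiguous.
    """

    n_shifts: int
    fc: float = 7.4
    fs: float = 250.0
    duration: float = 6.0
    noise_sd: float = 0.0
    seed: int = 0
    shift_magnitude_range: Tuple[float, float] = (np.pi / 8, 7 * np.pi / 8)
    min_gap: int = 25
    edge_margin: int = 150

    def __post_init__(self):
        if self.n_shifts < 0:
            raise ValueError("n_shifts must be nonnegative")
        if not (0 < self.fc < self.fs / 2):
            raise ValueError("fc must lie in (0, fs/2)")
        lo, hi = self.shift_magnitude_range
        if not (0 < lo <= hi):
            raise ValueError("invalid shift magnitude range")
        n = int(round(self.duration * self.fs))
        if self.n_shifts and self.n_shifts * self.min_gap + 2 * self.edge_margin >= n:
            raise ValueError(
                f"cannot place {self.n_shifts} shifts with min_gap={self.min_gap} and "
                f"edge_margin={self.edge_margin} in {n} samples"
            )


def _draw_separated_indices(rng, n_shifts, n, min_gap, edge_margin, max_tries=1000):
    lo, hi = edge_margin, n - edge_margin
    for _ in range(max_tries):
        idx = np.sort(rng.integers(lo, hi, size=n_shifts))
        if idx.size < 2 or np.all(np.diff(idx) >= min_gap):
            return idx
    raise ValueError("failed to draw separated shift indices; relax min_gap or n_shifts")


def generate_random_shifts(spec: RandomShiftSpec) -> LabeledSignal:
    """Generate the sinusoid with labeled random phase jumps."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)
    if spec.n_shifts:
        indices = _draw_separated_indices(rng, spec.n_shifts, n, spec.min_gap, spec.edge_margin)
        lo, hi = spec.shift_magnitude_range
        mags = rng.uniform(lo, hi, size=spec.n_shifts)
        signs = rng.choice([-1.0, 1.0], size=spec.n_shifts)
    else:
        indices = np.array([], dtype=int)
        mags = signs = np.array([])
    offset = np.zeros(n)
    for k, m, s in zip(indices, mags, signs):
        offset[k:] += s * m
    clean = np.sin(2 * np.pi * spec.fc * t + offset)
    noisy = clean + (rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0)
    return LabeledSignal(
        signal=RealSignal(noisy, fs=spec.fs),
        true_change_indices=indices,
        clean_signal=RealSignal(clean, fs=spec.fs),
    )


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """EEG-like superposition of sinusoids plus noise at an exact SNR.

    ``target_snr`` is ``var(clean) / var(noise)`` over the full record; the
    noise is white Gaussian, rescaled so the realized ratio matches the
    target exactly (up to floating point).
    """

    components: Tuple[Tuple[float, float, float], ...] = DEFAULT_EEG_COMPONENTS
    fs: float = 250.0
    duration: float = 10.0
    target_snr: float = 0.11
    seed: int = 0

    def __post_init__(self):
        comps = tuple((float(f), float(a), float(p)) for (f, a, p) in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("component list must not be empty")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        for f, _, _ in comps:
            if not (0 < f < self.fs / 2):
                raise ValueError(f"component frequency {f} Hz outside (0, fs/2)")


def generate_synthetic_eeg(spec: SyntheticEEGSpec) -> LabeledSignal:
    """Generate the sinusoid mixture with exactly scaled additive noise."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    clean = np.zeros(n)
    for f, a, ph in spec.components:
        clean += a * np.sin(2 * np.pi * f * t + ph)
    rng = np.random.default_rng(spec.seed)
    raw = rng.standard_normal(n)
    raw_var = raw.var()
    scale = np.sqrt(clean.var() / (spec.target_snr * raw_var))
    noisy = clean + scale * raw
    return LabeledSignal(
        signal=RealSignal(noisy, fs=spec.fs),
        true_change_indices=np.array([], dtype=int),
        clean_signal=RealSignal(clean, fs=spec.fs),
    )
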