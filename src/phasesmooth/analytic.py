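"""Analytic signals, phase/envelope decompositions and narrow-band filter ensembles.

The instantaneous phase (IP) and envelope (IE) of a real oscillatory signal
are obtained from its analytic form ``x + i H(x)``, with ``H`` the Hilbert
transform.  For a signal narrow-bandpassed around a center frequency ``fc``
the unwrapped phase grows almost linearly with slope ``omega0 = 2*pi*fc/fs``
radians per sample; the *residual* ``r(t) = p(t) - omega0*t`` isolates phase
resets as steps, and is the series all downstream smoothing and change-point
detection operate on.

Because the IP is an arctangent of two narrow-band quantities, samples where
the envelope approaches zero produce large, physically meaningless phase
excursions ("spurious phase variations").  This module provides the
decomposition itself, a low-envelope flag, and the robust ensemble of
slightly perturbed zero-phase elliptic band-pass filters used to quantify
how sensitive the extracted phase is to the filter parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "RealSignal",
    "AnalyticSignal",
    "PhaseDecomposition",
    "FilterSpec",
    "FilterEnsemble",
    "compute_analytic",
    "decompose",
    "flag_low_envelope",
    "bandpass_analytic",
    "ensemble_filter",
    "transient_mask",
]


@dataclass(frozen=True)
class RealSignal:
    """A real-valued, uniformly sampled time series.

    Parameters
    ----------
    samples : array-like of float
        The signal values (arbitrary units).  Must be finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    channel_id : str, optional
        Label of the originating channel.
    """

    samples: np.ndarray
    fs: float
    channel_id: Optional[str] = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (index / fs)."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class AnalyticSignal:
    """A complex analytic time series ``x + i H(x)``."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=complex)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("analytic signal must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("analytic signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PhaseDecomposition:
    """Per-sample envelope/phase decomposition of an analytic signal.

    Attributes
    ----------
    envelope : ndarray
        Instantaneous envelope ``A_t = |x_hat_t|`` (signal units, >= 0).
    wrapped_phase : ndarray
        Instantaneous phase ``theta(t) = atan2(u, x)`` in ``[-pi, pi)`` rad.
    unwrapped_phase : ndarray
        Cumulative-2*pi corrected phase ``p(t)`` in radians.
    residual : ndarray
        ``r(t) = p(t) - omega0 * t`` (t in samples), radians.
    inst_frequency : ndarray
        Angular instantaneous frequency ``z(t) = (p_t - p_{t-1}) * fs`` in
        rad/s; ``z(0)`` is copied from ``z(1)`` so all series share one length.
    omega0 : float
        Center angular frequency in rad/sample.
    fs : float
        Sampling rate in Hz.
    """

    envelope: np.ndarray
    wrapped_phase: np.ndarray
    unwrapped_phase: np.ndarray
    residual: np.ndarray
    inst_frequency: np.ndarray
    omega0: float
    fs: float

    def __len__(self) -> int:
        return self.envelope.size


def compute_analytic(x: RealSignal) -> AnalyticSignal:
    """Analytic form of a real signal via the Hilbert transform.

    Returns ``x_hat = x + i H(x)``; the real part equals the input and the
    imaginary part is its Hilbert transform (computed spectrally, so the
    construction is exact up to FFT round-off and periodic-extension edge
    effects).
    """
    if not isinstance(x, RealSignal):
        x = RealSignal(np.asarray(x, dtype=float), fs=getattr(x, "fs", 1.0))
    return AnalyticSignal(sps.hilbert(x.samples), fs=x.fs)


def _wrap_half_open(angles: np.ndarray) -> np.ndarray:
    # np.angle returns (-pi, pi]; fold the single point +pi onto -pi to get
    # the half-open convention [-pi, pi).
    wrapped = angles.copy()
    wrapped[wrapped == np.pi] = -np.pi
    return wrapped


def decompose_omega0(a: AnalyticSignal, omega0: float) -> PhaseDecomposition:
    """Decompose an analytic signal given the center frequency in rad/sample."""
    samples = a.samples
    envelope = np.abs(samples)
    wrapped = _wrap_half_open(np.angle(samples))
    unwrapped = np.unwrap(wrapped)
    residual = unwrapped - omega0 * np.arange(samples.size)
    dif = np.diff(unwrapped) * a.fs
    inst_frequency = np.concatenate(([dif[0]], dif))
    return PhaseDecomposition(
        envelope=envelope,
        wrapped_phase=wrapped,
        unwrapped_phase=unwrapped,
        residual=residual,
        inst_frequency=inst_frequency,
        omega0=omega0,
        fs=a.fs,
    )


def decompose(a: AnalyticSignal, fc: float) -> PhaseDecomposition:
    """Envelope, wrapped/unwrapped phase, residual and instantaneous frequency.

    Parameters
    ----------
    a : AnalyticSignal
    fc : float
        Center frequency in Hz; must satisfy ``0 < fc < fs/2``.
    """
    if not (0 < fc < a.fs / 2):
        raise ValueError(f"fc={fc} Hz outside the open Nyquist interval (0, {a.fs / 2})")
    omega0 = 2 * np.pi * fc / a.fs
    return decompose_omega0(a, omega0)


def flag_low_envelope(d: PhaseDecomposition, threshold: float) -> np.ndarray:
    """Boolean mask, true exactly where the envelope is below ``threshold``.

    Samples flagged true are candidates for spurious phase variation: the
    arctangent that defines the phase becomes ill-conditioned when both the
    real and imaginary parts of the analytic signal are small.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return d.envelope < threshold


@dataclass(frozen=True)
class FilterSpec:
    """Design of the zero-phase IIR elliptic narrow-band filter ensemble.

    Defaults follow the narrow-band EEG configuration: order-6 elliptic
    filter with 50 dB stop-band attenuation, 0.01 dB pass-band ripple,
    0.5 Hz total pass-band width, applied forward-backward (zero phase),
    with M = 100 ensemble members whose center frequency is independently
    perturbed by a relative amount uniform in
    ``[-perturbation_scale, +perturbation_scale]``.
    """

    fc: float
    bandwidth: float = 0.5
    order: int = 6
    stopband_atten: float = 50.0
    passband_ripple: float = 0.01
    perturbation_scale: float = 0.01
    M: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.fc <= 0:
            raise ValueError("fc must be positive")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.M < 1:
            raise ValueError("ensemble size M must be >= 1")
        if self.perturbation_scale < 0:
            raise ValueError("perturbation_scale must be nonnegative")

    def validate_against(self, fs: float) -> None:
        lo = self.fc - self.bandwidth / 2
        hi = self.fc + self.bandwidth / 2
        if not (0 < lo and hi < fs / 2):
            raise ValueError(
                f"pass band [{lo}, {hi}] Hz infeasible for fs={fs} Hz (Nyquist {fs / 2})"
            )


@dataclass(frozen=True)
class FilterEnsemble:
    """M analytic signals from slightly perturbed band-pass filters."""

    members: Sequence[AnalyticSignal]
    mean_signal: AnalyticSignal
    spec: FilterSpec
    center_frequencies: np.ndarray = field(default=None)

    def member_matrix(self) -> np.ndarray:
        """Stack the members into an (M, T) complex array."""
        return np.vstack([m.samples for m in self.members])


def _design_sos(spec: FilterSpec, fc: float, fs: float) -> np.ndarray:
    lo = fc - spec.bandwidth / 2
    hi = fc + spec.bandwidth / 2
    if not (0 < lo and hi < fs / 2):
        raise ValueError(
            f"filter design infeasible for member fc={fc:.6g} Hz "
            f"(band [{lo:.6g}, {hi:.6g}] Hz, fs={fs} Hz)"
        )
    return sps.ellip(
        spec.order,
        spec.passband_ripple,
        spec.stopband_atten,
        [lo, hi],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass_analytic(x: RealSignal, spec: FilterSpec, fc: Optional[float] = None) -> AnalyticSignal:
    """Zero-phase band-pass a signal and return its analytic form.

    Forward-backward (``sosfiltfilt``) application cancels the filter's phase
    response, so the band-passed signal is not delayed relative to the input.
    """
    fc = spec.fc if fc is None else fc
    sos = _design_sos(spec, fc, x.fs)
    y = sps.sosfiltfilt(sos, x.samples)
    return AnalyticSignal(sps.hilbert(y), fs=x.fs)


def ensemble_filter(x: RealSignal, spec: FilterSpec) -> FilterEnsemble:
    """Band-pass ``x`` with M slightly perturbed filters.

    Each member m uses center frequency ``fc * (1 + delta_m)`` with
    ``delta_m ~ Uniform(-perturbation_scale, +perturbation_scale)`` drawn from
    a generator seeded with ``spec.seed`` (bit-identical across runs).  The
    per-sample spread across members measures how sensitive the extracted
    analytic signal is to the filter design, and feeds the measurement-noise
    estimate of the smoother.
    """
    spec.validate_against(x.fs)
    rng = np.random.default_rng(spec.seed)
    deltas = rng.uniform(-spec.perturbation_scale, spec.perturbation_scale, size=spec.M)
    fcs = spec.fc * (1.0 + deltas)
    members = [bandpass_analytic(x, spec, fc=fc_m) for fc_m in fcs]
    mean = np.mean([m.samples for m in members], axis=0)
    return FilterEnsemble(
        members=members,
        mean_signal=AnalyticSignal(mean, fs=x.fs),
        spec=spec,
        center_frequencies=fcs,
    )


def transient_mask(n: int, fs: float, bandwidth: float) -> np.ndarray:
    """Companion mask flagging filter edge transients (true = unreliable).

    The first and last ``ceil(3 * fs / bandwidth)`` samples are flagged, a
    conservative multiple of the ~1/bandwidth impulse-response time scale of a
    narrow band-pass filter.  Samples are flagged rather than removed so all
    per-sample series stay aligned.
    """
    w = min(int(math.ceil(3.0 * fs / bandwidth)), n // 2)
    mask = np.zeros(n, dtype=bool)
    mask[:w] = True
    mask[n - w:] = True
    return mask
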