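"""Complex linear-Gaussian state-space smoother for narrow-band phase.

Model
-----
The clean narrow-band analytic signal ``s_t = A_t * exp(i(omega0 t + theta_t))``
has slowly varying envelope ``A_t`` and residual phase ``theta_t``, so the
ratio of successive samples is approximately ``exp(i omega0)``.  This yields
the state-space model

    s_{t+1} = exp(i omega0) s_t + eta_t,   eta_t ~ CN(0, sigma)
    x_t     = s_t + W_t,                   W_t   ~ CN(0, alpha)

where ``CN(0, v)`` denotes a circular complex Gaussian whose real and
imaginary components each have variance ``v``.  Splitting real and imaginary
parts gives an equivalent two-dimensional real model whose transition matrix
is the rotation ``B`` by ``omega0`` and whose covariances are all isotropic
(``v * I``).  Isotropy is preserved by every filtering and smoothing update,
so all covariances reduce to scalars and the recursions below are exact, not
approximations.  Internally the means are propagated as complex numbers —
multiplying by ``exp(i omega0)`` *is* the rotation ``B`` acting on
``(Re, Im)`` — which keeps the per-sample loop cheap.

Forward pass (Kalman filter), for t = 1..T-1:

    p' = p_t + sigma
    K_t = p' / (p' + alpha)
    mu_{t+1} = B mu_t + K_t (x_{t+1} - B mu_t)
    p_{t+1} = p' - K_t p' = p' alpha / (p' + alpha)

Backward pass (fixed-interval smoother), for t = T-1..1:

    g_t = p_t / (p_t + sigma)
    mu_bar_t = mu_t + g_t (B^T mu_bar_{t+1} - mu_t)
    p_bar_t = p_t + g_t^2 (p_bar_{t+1} - p_t - sigma)

The filtered variance converges to the Riccati fixed point
``p* = (-sigma + sqrt(sigma^2 + 4 sigma alpha)) / 2``.

Parameter estimation follows the moment identities of the model: the
per-component variance ``epsilon`` of the rotated first difference
``x_{t+1} - exp(i omega0) x_t`` equals ``sigma + 2 alpha`` when the
measurement noise is white, so ``sigma`` is admissible in
``[max(epsilon - 2 alpha, 0), epsilon]``; ``alpha`` is taken as the
cross-member variance of the perturbed-filter ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .analytic import (
    AnalyticSignal,
    FilterEnsemble,
    FilterSpec,
    PhaseDecomposition,
    RealSignal,
    decompose,
    decompose_omega0,
    ensemble_filter,
)

__all__ = [
    "KalmanParams",
    "FilterResult",
    "SmootherResult",
    "SigmaEstimate",
    "rotation_matrix",
    "riccati_fixed_point",
    "forward_pass",
    "backward_pass",
    "estimate_sigma",
    "estimate_alpha",
    "smooth_phase",
    "simulate_state_space",
]


@dataclass(frozen=True)
class KalmanParams:
    """Parameters of the complex linear-Gaussian phase model.

    Attributes
    ----------
    omega0 : float
        Center angular frequency in rad/sample.
    sigma : float
        Process-noise variance per real component (signal units squared).
        Controls how much genuine phase/envelope variation the model admits
        per sample; smaller values smooth harder.
    alpha : float
        Measurement-noise variance per real component.
    beta : float
        Nonnegative factor scaling the sigma estimate (``sigma = beta *
        epsilon``); the single user knob trading trust in the measurements
        against trust in the rotation prediction.  beta = 0 removes all
        phase variation (constant instantaneous frequency).
    mu1 : complex, optional
        Initial state mean; default: the first observation.
    p1 : float, optional
        Initial per-component state variance; default: diffuse,
        ``10 * (alpha + sigma)`` (or 1.0 if that is zero).
    """

    omega0: float
    sigma: float
    alpha: float
    beta: float = 0.5
    mu1: Optional[complex] = None
    p1: Optional[float] = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.p1 is not None and self.p1 <= 0:
            if self.alpha == 0 and self.sigma == 0:
                raise ValueError(
                    "degenerate model: alpha = sigma = 0 with p1 = 0 leaves the "
                    "gain undefined; give any of them a positive value"
                )
            raise ValueError("p1 must be positive")

    def initial(self, first_obs: complex) -> Tuple[complex, float]:
        mu1 = first_obs if self.mu1 is None else complex(self.mu1)
        if self.p1 is not None:
            p1 = float(self.p1)
        else:
            p1 = 10.0 * (self.alpha + self.sigma)
            if p1 == 0.0:
                p1 = 1.0
        return mu1, p1


def rotation_matrix(omega0: float) -> np.ndarray:
    """The 2x2 rotation ``B`` by ``omega0`` (orthogonal, det 1)."""
    c, s = np.cos(omega0), np.sin(omega0)
    return np.array([[c, -s], [s, c]])


def riccati_fixed_point(sigma: float, alpha: float) -> float:
    """Steady-state filtered variance ``p* = (-sigma + sqrt(sigma^2 + 4 sigma alpha)) / 2``."""
    return 0.5 * (-sigma + np.sqrt(sigma**2 + 4.0 * sigma * alpha))


def _as_complex(obs) -> Tuple[np.ndarray, float]:
    if isinstance(obs, AnalyticSignal):
        return obs.samples, obs.fs
    arr = np.asarray(obs)
    if arr.ndim == 2 and arr.shape[1] == 2:
        arr = arr[:, 0] + 1j * arr[:, 1]
    return arr.astype(complex), 1.0


def _as_vectors(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag])


@dataclass(frozen=True)
class FilterResult:
    """Output of the forward (filtering) pass.

    ``filtered_means`` holds the posterior means ``mu_t`` as (T, 2) real
    vectors, ``filtered_vars`` the scalar per-component variances ``p_t``
    (posterior covariance ``p_t * I``), and ``gains`` the scalar Kalman gains
    ``K_t`` (``gains[0] = 1`` by convention: the prior is anchored on the
    first observation).
    """

    filtered_means: np.ndarray
    filtered_vars: np.ndarray
    gains: np.ndarray
    params: KalmanParams
    fs: float = 1.0

    @property
    def filtered_complex(self) -> np.ndarray:
        return self.filtered_means[:, 0] + 1j * self.filtered_means[:, 1]


@dataclass(frozen=True)
class SmootherResult:
    """Output of the backward (smoothing) pass.

    ``smoothed_means``/``smoothed_vars`` are the full-record posteriors
    ``mu_bar_t``, ``p_bar_t``; the last entries equal the filtered ones.
    ``smoothed_phase`` is the phase decomposition of the smoothed complex
    sequence; ``pre_phase`` (when produced by :func:`smooth_phase`) is the
    decomposition of the observations before smoothing, for comparison.
    """

    smoothed_means: np.ndarray
    smoothed_vars: np.ndarray
    smoothed_phase: PhaseDecomposition
    params: KalmanParams
    fs: float = 1.0
    pre_phase: Optional[PhaseDecomposition] = None
    diagnostics: Optional[dict] = None

    @property
    def smoothed_complex(self) -> np.ndarray:
        return self.smoothed_means[:, 0] + 1j * self.smoothed_means[:, 1]


def forward_pass(obs, params: KalmanParams) -> FilterResult:
    """Kalman filter with scalar (isotropic) covariances.

    ``obs`` may be an :class:`AnalyticSignal`, a complex array, or a (T, 2)
    real array of (Re, Im) vectors.  Deterministic: identical inputs give
    identical outputs.
    """
    z, fs = _as_complex(obs)
    if z.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(z)):
        raise ValueError("observations contain non-finite values")
    sigma, alpha = params.sigma, params.alpha
    if alpha == 0 and sigma == 0 and params.p1 is not None and params.p1 <= 0:
        raise ValueError("degenerate model: alpha = sigma = 0 with p1 <= 0")

    T = z.size
    rot = complex(np.cos(params.omega0), np.sin(params.omega0))
    mu = np.empty(T, dtype=complex)
    p = np.empty(T)
    K = np.empty(T)
    mu[0], p[0] = params.initial(z[0])
    K[0] = 1.0
    for t in range(T - 1):
        pp = p[t] + sigma
        denom = pp + alpha
        k = 1.0 if denom == 0.0 else pp / denom
        pred = rot * mu[t]
        mu[t + 1] = pred + k * (z[t + 1] - pred)
        p[t + 1] = pp - k * pp
        K[t + 1] = k
    return FilterResult(
        filtered_means=_as_vectors(mu),
        filtered_vars=p,
        gains=K,
        params=params,
        fs=fs,
    )


def backward_pass(fr: FilterResult, params: Optional[KalmanParams] = None) -> SmootherResult:
    """Fixed-interval smoother matching :func:`forward_pass`.

    Runs the backward recursion from the last filtered state; the smoothed
    posterior at T equals the filtered one, and smoothing never increases the
    posterior variance.
    """
    if params is None:
        params = fr.params
    elif params.omega0 != fr.params.omega0:
        raise ValueError("params do not match the forward pass (omega0 differs)")
    sigma = params.sigma
    mu = fr.filtered_complex
    p = fr.filtered_vars
    if mu.size != p.size:
        raise ValueError("inconsistent forward-pass result")
    T = mu.size
    rot_conj = complex(np.cos(params.omega0), -np.sin(params.omega0))
    mus = np.empty(T, dtype=complex)
    ps = np.empty(T)
    mus[T - 1] = mu[T - 1]
    ps[T - 1] = p[T - 1]
    for t in range(T - 2, -1, -1):
        denom = p[t] + sigma
        g = 0.0 if denom == 0.0 else p[t] / denom
        mus[t] = mu[t] + g * (rot_conj * mus[t + 1] - mu[t])
        ps[t] = p[t] + g * g * (ps[t + 1] - p[t] - sigma)
    smoothed = AnalyticSignal(mus, fs=fr.fs)
    phase = decompose_omega0(smoothed, params.omega0)
    return SmootherResult(
        smoothed_means=_as_vectors(mus),
        smoothed_vars=ps,
        smoothed_phase=phase,
        params=params,
        fs=fr.fs,
    )


@dataclass(frozen=True)
class SigmaEstimate:
    """Moment-based estimate of the process-noise variance.

    ``epsilon`` is the per-component sample variance of the rotated first
    difference of the observations; under white measurement noise it equals
    ``sigma + 2 alpha``, so the admissible range for ``sigma`` is
    ``[max(epsilon - 2 alpha, 0), epsilon]``.  ``sigma_point`` is the working
    value ``clip(beta * epsilon, 0, epsilon)``; beta = 0 deliberately selects
    sigma = 0 (maximal smoothing: the smoothed instantaneous frequency
    collapses to a constant).
    """

    epsilon: float
    sigma_range: Tuple[float, float]
    sigma_point: float


def estimate_sigma(obs, omega0: float, alpha: float, beta: float = 0.5) -> SigmaEstimate:
    """Estimate the process-noise variance from differenced observations."""
    z, _ = _as_complex(obs)
    if z.size < 3:
        raise ValueError("need at least 3 observations to difference and take a variance")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    rot = complex(np.cos(omega0), np.sin(omega0))
    d = z[1:] - rot * z[:-1]
    epsilon = 0.5 * (np.var(d.real, ddof=1) + np.var(d.imag, ddof=1))
    if epsilon == 0.0:
        warnings.warn("observations have a constant rotated difference; sigma estimate is 0")
    lo = max(epsilon - 2.0 * alpha, 0.0)
    point = float(np.clip(beta * epsilon, 0.0, epsilon))
    return SigmaEstimate(epsilon=float(epsilon), sigma_range=(float(lo), float(epsilon)), sigma_point=point)


def estimate_alpha(ens: FilterEnsemble, mode: str = "signal") -> float:
    """Measurement-noise variance from the perturbed-filter ensemble.

    mode = "signal" (default): per-sample cross-member variance of the real
    and imaginary parts of the analytic members, averaged over samples and
    components.  This has the signal's units squared, matching alpha's role
    in the observation equation.

    mode = "phase": per-sample cross-member variance of the members'
    instantaneous phases (radians squared), after centering each member's
    phase on the ensemble mean signal to avoid wrap-around artifacts.
    Provided for comparison only; its units differ from alpha's.
    """
    if ens.spec.M < 2 or len(ens.members) < 2:
        raise ValueError("alpha estimation requires an ensemble with M >= 2")
    mat = ens.member_matrix()
    if mode == "signal":
        v_re = np.var(mat.real, axis=0, ddof=1)
        v_im = np.var(mat.imag, axis=0, ddof=1)
        return float(0.5 * (v_re.mean() + v_im.mean()))
    if mode == "phase":
        ref = ens.mean_signal.samples
        # angle of member relative to the ensemble mean; wrap-safe
        deltas = np.angle(mat * np.conj(ref)[None, :])
        return float(np.var(deltas, axis=0, ddof=1).mean())
    raise ValueError(f"unknown alpha estimation mode: {mode!r}")


def smooth_phase(
    x: RealSignal,
    spec: FilterSpec,
    beta: float = 0.5,
    sigma: Optional[float] = None,
    alpha: Optional[float] = None,
    alpha_mode: str = "signal",
) -> SmootherResult:
    """Full pipeline: filter ensemble -> parameter estimates -> smoother.

    Band-passes ``x`` with the perturbed-filter ensemble, estimates the
    measurement noise ``alpha`` from the cross-member spread and the process
    noise ``sigma`` from the differenced ensemble-mean analytic signal
    (unless explicit overrides are given), then runs the forward and backward
    passes on the ensemble mean.  The result carries both the pre- and
    post-smoothing phase decompositions plus a diagnostics dict
    (epsilon, alpha, sigma range, Riccati fixed point).
    """
    try:
        ens = ensemble_filter(x, spec)
    except Exception as e:
        raise RuntimeError(f"[ensemble_filter] {e}") from e
    try:
        alpha_hat = float(alpha) if alpha is not None else estimate_alpha(ens, mode=alpha_mode)
    except Exception as e:
        raise RuntimeError(f"[estimate_alpha] {e}") from e
    obs = ens.mean_signal
    omega0 = 2 * np.pi * spec.fc / x.fs
    try:
        se = estimate_sigma(obs, omega0, alpha_hat, beta)
    except Exception as e:
        raise RuntimeError(f"[estimate_sigma] {e}") from e
    sigma_hat = float(sigma) if sigma is not None else se.sigma_point
    params = KalmanParams(omega0=omega0, sigma=sigma_hat, alpha=alpha_hat, beta=beta)
    try:
        fr = forward_pass(obs, params)
        sr = backward_pass(fr, params)
    except Exception as e:
        raise RuntimeError(f"[smoother] {e}") from e
    pre = decompose(obs, spec.fc)
    diagnostics = {
        "epsilon": se.epsilon,
        "alpha": alpha_hat,
        "sigma": sigma_hat,
        "sigma_range": list(se.sigma_range),
        "beta": beta,
        "p_star": float(riccati_fixed_point(sigma_hat, alpha_hat)),
    }
    return replace(sr, pre_phase=pre, diagnostics=diagnostics)


def simulate_state_space(
    omega0: float,
    sigma: float,
    alpha: float,
    T: int,
    seed: int = 0,
    s1: complex = 1.0 + 0.0j,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (states, observations) from the generative model.

    States follow ``s_{t+1} = exp(i omega0) s_t + eta_t`` with circular
    complex Gaussian noise of per-component variance ``sigma``; observations
    add independent noise of per-component variance ``alpha``.  Used for
    parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    rot = complex(np.cos(omega0), np.sin(omega0))
    eta = rng.normal(0, np.sqrt(sigma), size=(T - 1, 2)) if sigma > 0 else np.zeros((T - 1, 2))
    s = np.empty(T, dtype=complex)
    s[0] = s1
    for t in range(T - 1):
        s[t + 1] = rot * s[t] + complex(eta[t, 0], eta[t, 1])
    w = rng.normal(0, np.sqrt(alpha), size=(T, 2)) if alpha > 0 else np.zeros((T, 2))
    x = s + w[:, 0] + 1j * w[:, 1]
    return s, x
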