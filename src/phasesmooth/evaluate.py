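"""Change-point detection on phase residuals, scoring, and the benchmark grid.

A genuine phase reset appears in the residual ``r(t)`` as a step in the
mean; spurious low-envelope jitter appears as transient excursions.  The
evaluation protocol detects mean shifts in the residual before and after
smoothing, matches detections to the known reset indices within a 10-sample
tolerance, and scores true/false positives and negatives plus the Matthews
correlation coefficient (MCC).

The detector is binary segmentation minimizing within-segment squared error
around segment means.  A split is accepted when it reduces the squared error
by more than an absolute penalty expressed in the residual's own units
(radians squared times samples): the default of 10 corresponds to the
smallest genuine reset magnitude of the protocol, pi/8 rad, sustained over
roughly 130 samples.  An absolute penalty is deliberate — a detected change
must be large on the physical phase scale, so the same detector applied
before and after smoothing measures how many *physically sizeable* mean
shifts each residual contains, rather than re-normalizing to each residual's
own noise floor.  Each accepted split is then re-localized by a local
two-mean fit in a window around it (narrow-band filtering smears a step
into a symmetric ramp; the local fit recovers the ramp center), and splits
that converge to nearly the same sample are merged.  The detector is
deterministic and verifiable against exhaustive segmentation on small
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytic import FilterSpec, RealSignal, bandpass_analytic, decompose
from .kalman import KalmanParams, backward_pass, estimate_sigma, forward_pass
from .synthetic import RandomShiftSpec, generate_random_shifts

__all__ = [
    "DetectorConfig",
    "ChangePointReport",
    "BenchmarkConfig",
    "BenchmarkResult",
    "detect_change_points",
    "score",
    "run_benchmark",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Settings of the mean-shift change-point detector.

    ``penalty`` is the absolute squared-error reduction (series units
    squared times samples) a split must achieve to be accepted; for phase
    residuals in radians the default 10 admits a pi/8 rad step sustained
    over ~130 samples.  ``min_segment`` is the minimum distance (samples)
    between change points and from the record ends; ``refine_window`` is the
    half-width of the local re-localization fit; ``tolerance`` is the
    matching tolerance used by the scorer (samples).
    """

    method: str = "binseg"
    min_segment: int = 20
    penalty: float = 10.0
    tolerance: int = 10
    refine_window: int = 60
    merge_window: int = 60

    def __post_init__(self):
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        if self.tolerance < 0:
            raise ValueError("tolerance must be nonnegative")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.refine_window < 0:
            raise ValueError("refine_window must be nonnegative")
        if self.method != "binseg":
            raise ValueError(f"unknown change-point method: {self.method!r}")


def _best_split(y2cum, ycum, a, b, min_segment):
    """Best single split of segment [a, b) by squared-error reduction."""
    ks = np.arange(a + min_segment, b - min_segment + 1)
    if ks.size == 0:
        return -1, 0.0
    n = b - a
    s_tot = ycum[b] - ycum[a]
    s2_tot = y2cum[b] - y2cum[a]
    cost_tot = s2_tot - s_tot**2 / n
    s_left = ycum[ks] - ycum[a]
    n_left = ks - a
    n_right = b - ks
    s_right = s_tot - s_left
    cost_split = (y2cum[ks] - y2cum[a] - s_left**2 / n_left) + (
        y2cum[b] - y2cum[ks] - s_right**2 / n_right
    )
    gains = cost_tot - cost_split
    i = int(np.argmax(gains))
    return int(ks[i]), float(gains[i])


def detect_change_points(residual: Sequence[float], cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Detect mean shifts in a residual series by binary segmentation.

    Returns strictly increasing sample indices (the first index of each new
    segment), pairwise separated by at least ``cfg.min_segment``.
    Deterministic for fixed input and configuration.
    """
    y = np.asarray(residual, dtype=float)
    if y.ndim != 1:
        raise ValueError("residual series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("residual series contains non-finite values")
    n = y.size
    if n <= 2 * cfg.min_segment:
        raise ValueError(f"series of length {n} too short for min_segment={cfg.min_segment}")
    ycum = np.concatenate(([0.0], np.cumsum(y)))
    y2cum = np.concatenate(([0.0], np.cumsum(y * y)))
    found: List[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        k, gain = _best_split(y2cum, ycum, a, b, cfg.min_segment)
        if k >= 0 and gain > cfg.penalty:
            found.append(k)
            stack.append((a, k))
            stack.append((k, b))
    found.sort()
    if cfg.refine_window > 0 and found:
        refined = []
        for i, k in enumerate(found):
            # clip the local window at the midpoints to neighboring splits so
            # re-localization cannot lock onto an adjacent change point
            lo = 0 if i == 0 else (found[i - 1] + k) // 2
            hi = n if i == len(found) - 1 else (k + found[i + 1]) // 2
            a = max(k - cfg.refine_window, lo)
            b = min(k + cfg.refine_window, hi)
            if b - a >= 10:
                kk, _ = _best_split(y2cum, ycum, a, b, 5)
                if kk >= 0:
                    k = kk
            refined.append(k)
        # merge splits that converged onto (nearly) the same transition
        found = []
        for k in sorted(refined):
            if found and k - found[-1] < cfg.min_segment:
                found[-1] = (found[-1] + k) // 2
            else:
                found.append(k)
    if cfg.merge_window > 0 and len(found) > 1:
        found = _merge_ramp_pairs(y, ycum, y2cum, found, cfg)
    return np.array(found, dtype=int)


def _segment_mean(ycum, a, b):
    return (ycum[b] - ycum[a]) / (b - a)


def _merge_ramp_pairs(y, ycum, y2cum, found, cfg):
    """Collapse split pairs that bracket a single monotone transition.

    A step smeared by narrow-band filtering (and further by smoothing) looks
    like a ramp; binary segmentation may place one split at each end of it.
    When two adjacent splits are closer than ``merge_window`` and the level
    between them lies between the outer levels (a staircase, i.e. one
    monotone transition), they are replaced by the best single split of the
    surrounding window — the ramp center.
    """
    n = y.size
    out = list(found)
    i = 0
    while i < len(out) - 1:
        k1, k2 = out[i], out[i + 1]
        if k2 - k1 < cfg.merge_window:
            lo = 0 if i == 0 else out[i - 1]
            hi = n if i + 2 >= len(out) else out[i + 2]
            a = max(lo, k1 - cfg.merge_window)
            b = min(hi, k2 + cfg.merge_window)
            left = _segment_mean(ycum, a, k1)
            mid = _segment_mean(ycum, k1, k2)
            right = _segment_mean(ycum, k2, b)
            if min(left, right) <= mid <= max(left, right):
                kk, _ = _best_split(y2cum, ycum, a, b, 5)
                out[i] = kk if kk >= 0 else (k1 + k2) // 2
                del out[i + 1]
                if i > 0:
                    i -= 1  # re-check against the new left neighbor
                continue
        i += 1
    return out


@dataclass(frozen=True)
class ChangePointReport:
    """Detection counts and MCC for one residual series."""

    detected: np.ndarray
    truth: np.ndarray
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float

    def to_dict(self) -> dict:
        return {
            "detected": [int(i) for i in self.detected],
            "truth": [int(i) for i in self.truth],
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "mcc": self.mcc,
        }


def matthews_corrcoef(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 when any factor is 0."""
    denom2 = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0.0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def score(
    detected: Iterable[int],
    truth: Iterable[int],
    tolerance: int = 10,
    series_length: int = 0,
) -> ChangePointReport:
    """Match detections to ground truth and score TP/FP/FN/TN and MCC.

    Matching is greedy by increasing distance and one-to-one: a detection
    within ``tolerance`` samples of an unmatched truth index is a true
    positive; leftover detections are false positives and leftover truths
    false negatives.  Every sample of the series is treated as a candidate
    event, so ``TN = series_length - TP - FP - FN``.
    """
    det = np.sort(np.asarray(list(detected), dtype=int))
    tru = np.sort(np.asarray(list(truth), dtype=int))
    if series_length <= 0:
        raise ValueError("series_length must be positive")
    for arr, name in ((det, "detected"), (tru, "truth")):
        if arr.size and (arr.min() < 0 or arr.max() >= series_length):
            raise ValueError(f"{name} indices outside [0, {series_length})")
    pairs = []
    for i, d in enumerate(det):
        for j, t in enumerate(tru):
            dist = abs(int(d) - int(t))
            if dist <= tolerance:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    fp = det.size - tp
    fn = tru.size - tp
    tn = series_length - tp - fp - fn
    if tn < 0:
        raise ValueError("more events than samples; check inputs")
    return ChangePointReport(
        detected=det,
        truth=tru,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        mcc=matthews_corrcoef(tp, fp, fn, tn),
    )


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid of the synthetic change-point benchmark.

    The full-scale protocol uses 2000 batches per cell on 1500-sample
    signals; the default here is the scaled variant (200 batches) with
    n in {1..4} true shifts and eight SNR levels concentrated in the
    high-noise regime the smoother targets.
    """

    n_change_points: Tuple[int, ...] = (1, 2, 3, 4)
    snr_grid: Tuple[float, ...] = (0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 1.0, 2.0)
    batches_per_cell: int = 200
    signal_length: int = 1500
    fs: float = 250.0
    fc: float = 7.4
    bandwidth: float = 4.0
    beta: Optional[float] = None  # None -> oracle sigma from the clean signal
    seed: int = 0

    def __post_init__(self):
        if self.batches_per_cell < 1 or self.signal_length < 100:
            raise ValueError("batches_per_cell must be >= 1 and signal_length >= 100")
        if any(n < 0 for n in self.n_change_points):
            raise ValueError("n_change_points must be nonnegative")
        if any(s <= 0 for s in self.snr_grid):
            raise ValueError("snr values must be positive")


@dataclass(frozen=True)
class BenchmarkResult:
    """Tidy per-cell table: n, snr, condition, mean_fp, mean_fn, mean_mcc."""

    table: pd.DataFrame
    config: BenchmarkConfig
    failures: int = 0

    def cell(self, n: int, snr: float, condition: str) -> pd.Series:
        t = self.table
        row = t[(t.n == n) & (np.isclose(t.snr, snr)) & (t.condition == condition)]
        if row.empty:
            raise KeyError(f"no cell (n={n}, snr={snr}, condition={condition})")
        return row.iloc[0]


def _oracle_params(labeled, fspec: FilterSpec, omega0: float):
    """Smoother parameters from the known clean/noise decomposition.

    alpha: per-component variance of the band-passed analytic noise;
    sigma: per-component variance of the rotated first difference of the
    band-passed clean analytic signal (exactly var(eta) of the state model).
    """
    noise = labeled.noise
    noise_a = bandpass_analytic(RealSignal(noise, fs=labeled.signal.fs), fspec)
    alpha = 0.5 * (np.var(noise_a.samples.real) + np.var(noise_a.samples.imag))
    clean_a = bandpass_analytic(labeled.clean_signal, fspec)
    sigma = estimate_sigma(clean_a, omega0, alpha=0.0, beta=1.0).epsilon
    return sigma, alpha


def run_benchmark(
    bcfg: BenchmarkConfig = BenchmarkConfig(),
    detector: DetectorConfig = DetectorConfig(),
    filter_spec: Optional[FilterSpec] = None,
    progress: bool = False,
) -> BenchmarkResult:
    """Run the pre- vs post-smoothing change-point benchmark grid.

    For each (n, SNR, batch): generate a random-shift sinusoid at that SNR,
    band-pass it, detect mean shifts in the phase residual before and after
    Kalman smoothing, and score against the known shift indices.  Smoother
    parameters per batch come from the known clean/noise split of the
    generated signal (the generator retains the noiseless signal), matching
    the protocol in which the true signal is available for synthetic data.
    Per-batch failures are counted, not silently dropped.  Fully reproducible
    under ``bcfg.seed``.
    """
    if filter_spec is None:
        filter_spec = FilterSpec(fc=bcfg.fc, bandwidth=bcfg.bandwidth, M=1, perturbation_scale=0.0)
    duration = bcfg.signal_length / bcfg.fs
    omega0 = 2 * np.pi * bcfg.fc / bcfg.fs
    ss = np.random.SeedSequence(bcfg.seed)
    n_cells = len(bcfg.n_change_points) * len(bcfg.snr_grid)
    cell_seeds = ss.spawn(n_cells)
    rows = []
    failures = 0
    cell_i = 0
    for n in bcfg.n_change_points:
        for snr in bcfg.snr_grid:
            batch_seeds = cell_seeds[cell_i].generate_state(bcfg.batches_per_cell) % (2**31)
            cell_i += 1
            agg = {c: np.zeros(3) for c in ("pre", "post")}
            n_ok = 0
            for b in range(bcfg.batches_per_cell):
                try:
                    spec = RandomShiftSpec(
                        n_shifts=n,
                        fc=bcfg.fc,
                        fs=bcfg.fs,
                        duration=duration,
                        noise_sd=float(np.sqrt(0.5 / snr)),
                        seed=int(batch_seeds[b]),
                    )
                    labeled = generate_random_shifts(spec)
                    obs = bandpass_analytic(labeled.signal, filter_spec)
                    pre = decompose(obs, bcfg.fc)
                    sigma, alpha = _oracle_params(labeled, filter_spec, omega0)
                    if bcfg.beta is not None:
                        se = estimate_sigma(obs, omega0, alpha, bcfg.beta)
                        sigma = se.sigma_point
                    params = KalmanParams(omega0=omega0, sigma=sigma, alpha=alpha)
                    sr = backward_pass(forward_pass(obs, params))
                    reports = {}
                    for cond, resid in (("pre", pre.residual), ("post", sr.smoothed_phase.residual)):
                        det = detect_change_points(resid, detector)
                        reports[cond] = score(
                            det,
                            labeled.true_change_indices,
                            tolerance=detector.tolerance,
                            series_length=bcfg.signal_length,
                        )
                    for cond, rep in reports.items():
                        agg[cond] += (rep.fp, rep.fn, rep.mcc)
                    n_ok += 1
                except Exception:
                    failures += 1
            for cond in ("pre", "post"):
                m = agg[cond] / max(n_ok, 1)
                rows.append(
                    {
                        "n": n,
                        "snr": snr,
                        "condition": cond,
                        "mean_fp": m[0],
                        "mean_fn": m[1],
                        "mean_mcc": m[2],
                        "batches": n_ok,
                    }
                )
            if progress:
                print(f"cell n={n} snr={snr}: done ({n_ok} batches)")
    table = pd.DataFrame(rows)
    return BenchmarkResult(table=table, config=bcfg, failures=failures)
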