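"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the scalar-covariance simplifications of the
package: the Kalman filter/smoother here carries full 2x2 covariance
matrices in the textbook matrix form, and the segmentation oracle is an
exhaustive search over split combinations.  They are slow and simple on
purpose.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def matrix_kalman_filter(obs: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray,
                         mu1: np.ndarray, P1: np.ndarray):
    """Textbook linear-Gaussian Kalman filter with full covariance matrices.

    obs: (T, d) observations; state transition x_{t+1} = B x_t + w,
    w ~ N(0, Q); observation y_t = x_t + v, v ~ N(0, R).  The initial
    posterior at t=0 is (mu1, P1); the innovation at step t uses obs[t+1].
    Returns (means (T, d), covs (T, d, d), gains list of (d, d)).
    """
    T, d = obs.shape
    I = np.eye(d)
    means = np.zeros((T, d))
    covs = np.zeros((T, d, d))
    gains = [np.eye(d)]
    means[0] = mu1
    covs[0] = P1
    for t in range(T - 1):
        P_pred = B @ covs[t] @ B.T + Q
        K = P_pred @ np.linalg.inv(P_pred + R)
        m_pred = B @ means[t]
        means[t + 1] = m_pred + K @ (obs[t + 1] - m_pred)
        covs[t + 1] = P_pred - K @ P_pred
        gains.append(K)
    return means, covs, gains


def matrix_rts_smoother(means: np.ndarray, covs: np.ndarray, B: np.ndarray, Q: np.ndarray):
    """Textbook Rauch-Tung-Striebel smoother matching matrix_kalman_filter."""
    T, d = means.shape
    sm = means.copy()
    sc = covs.copy()
    for t in range(T - 2, -1, -1):
        P_pred = B @ covs[t] @ B.T + Q
        G = covs[t] @ B.T @ np.linalg.inv(P_pred)
        sm[t] = means[t] + G @ (sm[t + 1] - B @ means[t])
        sc[t] = covs[t] + G @ (sc[t + 1] - P_pred) @ G.T
    return sm, sc


def segment_cost(y: np.ndarray, splits) -> float:
    """Total within-segment squared error around segment means."""
    bounds = [0, *sorted(splits), y.size]
    cost = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = y[a:b]
        cost += float(np.sum((seg - seg.mean()) ** 2))
    return cost


def brute_force_segmentation(y: np.ndarray, penalty: float, min_segment: int, max_splits: int = 2):
    """Exhaustive least-squares segmentation with a per-split penalty.

    Evaluates every combination of up to ``max_splits`` split points that
    respects ``min_segment`` and returns the combination minimizing
    total cost + penalty * n_splits.
    """
    n = y.size
    candidates = range(min_segment, n - min_segment + 1)
    best = ((), segment_cost(y, ()))
    for k in range(1, max_splits + 1):
        for combo in combinations(candidates, k):
            if any(b - a < min_segment for a, b in zip(combo[:-1], combo[1:])):
                continue
            c = segment_cost(y, combo) + penalty * k
            if c < best[1]:
                best = (combo, c)
    return np.array(best[0], dtype=int)
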