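"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (enumeration,
grid search, textbook formulas) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# quality-threshold clustering by exhaustive subset search


def _min_pairwise(C: np.ndarray, subset) -> float:
    subset = list(subset)
    if len(subset) < 2:
        return 1.0
    best = math.inf
    for a, b in itertools.combinations(subset, 2):
        best = min(best, C[a, b])
    return best


def exhaustive_qt(C: np.ndarray, min_size: int, min_corr: float
                  ) -> list[list[int]]:
    """Iteratively emit the largest subset with min pairwise correlation
    >= min_corr (ties broken by higher quality), by brute-force enumeration."""
    remaining = list(range(C.shape[0]))
    clusters: list[list[int]] = []
    while len(remaining) >= min_size:
        best: tuple[int, ...] | None = None
        best_q = -math.inf
        for size in range(len(remaining), 1, -1):
            for comb in itertools.combinations(remaining, size):
                q = _min_pairwise(C, comb)
                if q >= min_corr and (best is None or q > best_q + 1e-12):
                    best, best_q = comb, q
            if best is not None:
                break  # largest feasible size found; ties resolved above
        if best is None or len(best) < min_size:
            break
        clusters.append(sorted(best))
        remaining = [i for i in remaining if i not in best]
    return clusters


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron) by direct summation + grid search


def efron_loglik(beta: float, x: np.ndarray, times: np.ndarray,
                 events: np.ndarray) -> float:
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        sum_r = np.exp(beta * x[R]).sum()
        sum_d = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for ell in range(d):
            ll -= math.log(sum_r - (ell / d) * sum_d)
    return ll


def grid_search_cox_beta(x: np.ndarray, times: np.ndarray,
                         events: np.ndarray, lo: float = -5.0,
                         hi: float = 5.0) -> float:
    """Maximize the Efron partial likelihood by nested grid scans (~1e-5)."""
    beta = 0.0
    for _ in range(4):
        grid = np.linspace(lo, hi, 401)
        lls = [efron_loglik(b, x, times, events) for b in grid]
        beta = float(grid[int(np.argmax(lls))])
        span = (hi - lo) / 400
        lo, hi = beta - 2 * span, beta + 2 * span
    return beta


# ---------------------------------------------------------------------------
# two-group log-rank by the O-E formula


def hand_logrank(times: np.ndarray, events: np.ndarray,
                 in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-square computed from observed-minus-expected."""
    O1 = E1 = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_group1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V if V > 0 else 0.0


def scan_cutpoint(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                  min_group_fraction: float) -> tuple[float, float]:
    """Literal scan over midpoint candidates; returns (tau, chi2).

    Ties on the statistic go to the smaller High group, as the classifier
    documents.
    """
    distinct = np.unique(scores)
    n = len(scores)
    best_tau, best_stat, best_nh = None, -math.inf, n + 1
    for tau in (distinct[:-1] + distinct[1:]) / 2:
        high = scores > tau
        nh = int(high.sum())
        if nh < min_group_fraction * n or (n - nh) < min_group_fraction * n:
            continue
        stat = hand_logrank(times, events, high)
        tol = 1e-9 * max(1.0, abs(best_stat))
        if stat > best_stat + tol or (abs(stat - best_stat) <= tol
                                      and nh < best_nh):
            best_tau, best_stat, best_nh = float(tau), stat, nh
    if best_tau is None:
        raise ValueError("no admissible candidate")
    return best_tau, best_stat
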