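"""Benjamini–Yekutieli FDR control over correlation-matrix p-values.

A whole-matrix multiple-comparison correction: the strict lower triangle
of a within-run p-value matrix (all entries for a cross-run null matrix)
is thresholded once by the Benjamini–Yekutieli step-up procedure, which
controls the false discovery rate at level γ under arbitrary dependence —
appropriate for spatially autocorrelated maps with both positive and
negative correlations.

Procedure: rank the N p-values ascending; let k* be the largest k with
p_(k) < (k/N) · γ / Σ_{j=1..N} 1/j; reject the k* smallest. The harmonic
sum is computed directly. The strict inequality is kept as printed; ties
with the boundary p-value share its fate via a stable (p, index) sort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FdrResult",
    "SensitivityMap",
    "by_procedure",
    "threshold_matrix",
    "sensitivity_map",
    "false_positive_summary",
    "fwe_naive_rate",
    "default_gamma_grid",
]


def default_gamma_grid(n: int = 13) -> np.ndarray:
    """Log-spaced FDR levels spanning the sweep 10⁻⁵ .. 10⁻²."""
    return np.logspace(-5, -2, n)


@dataclass(frozen=True)
class FdrResult:
    """Outcome of one Benjamini–Yekutieli thresholding."""

    gamma: float
    k_star: int
    p_threshold: float
    reject: np.ndarray           # boolean, same shape as the tested p input
    n_tested: int
    percent_significant: float
    mode: str = "vector"         # vector | within_run | cross_null


def _by_reject_flat(p: np.ndarray, gamma: float) -> tuple[np.ndarray, int, float]:
    n = p.size
    if n == 0:
        raise ValueError("no p-values to threshold")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    order = np.lexsort((np.arange(n), p))  # stable on (p, index)
    ps = p[order]
    harmonic = (1.0 / np.arange(1, n + 1)).sum()
    thresh = np.arange(1, n + 1) * gamma / (n * harmonic)
    passing = np.flatnonzero(ps < thresh)
    reject = np.zeros(n, dtype=bool)
    if passing.size == 0:
        return reject, 0, 0.0
    k_star = int(passing[-1]) + 1
    reject[order[:k_star]] = True
    return reject, k_star, float(ps[k_star - 1])


def by_procedure(p_values: np.ndarray, gamma: float) -> FdrResult:
    """Benjamini–Yekutieli step-up on a flat collection of p-values."""
    p = np.ravel(np.asarray(p_values, dtype=float))
    reject, k_star, p_thr = _by_reject_flat(p, gamma)
    return FdrResult(gamma=float(gamma), k_star=k_star, p_threshold=p_thr,
                     reject=reject.reshape(np.shape(p_values)),
                     n_tested=p.size,
                     percent_significant=100.0 * k_star / p.size)


def threshold_matrix(P: np.ndarray, gamma: float,
                     mode: str = "within_run") -> FdrResult:
    """BY-threshold a p-value matrix in one pass.

    ``within_run``: the matrix is symmetric; only the strict lower
    triangle is tested (N = P(P−1)/2) and rejections are mirrored into a
    symmetric mask with a false diagonal. ``cross_null``: every entry is a
    distinct test (N = Pa·Pb).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("expected a 2-D p-value matrix")
    if mode == "within_run":
        if P.shape[0] != P.shape[1]:
            raise ValueError("within-run p-value matrix must be square")
        rows, cols = np.tril_indices(P.shape[0], k=-1)
        flat = P[rows, cols]
        reject_flat, k_star, p_thr = _by_reject_flat(flat, gamma)
        mask = np.zeros(P.shape, dtype=bool)
        mask[rows[reject_flat], cols[reject_flat]] = True
        mask |= mask.T
    elif mode == "cross_null":
        flat = P.ravel()
        reject_flat, k_star, p_thr = _by_reject_flat(flat, gamma)
        mask = reject_flat.reshape(P.shape)
    else:
        raise ValueError("mode must be 'within_run' or 'cross_null'")
    n = flat.size
    return FdrResult(gamma=float(gamma), k_star=k_star, p_threshold=p_thr,
                     reject=mask, n_tested=n,
                     percent_significant=100.0 * k_star / n, mode=mode)


@dataclass(frozen=True)
class SensitivityMap:
    """Per-pair smallest FDR level at which the pair is rejected.

    ``min_gamma`` is ∞ for pairs never significant on the grid; because
    BY rejection sets are nested in γ, once a pair is rejected at some
    grid level it stays rejected at all larger levels.
    """

    gamma_grid: np.ndarray
    min_gamma: np.ndarray
    mode: str


def sensitivity_map(P: np.ndarray, gamma_grid: np.ndarray | None = None,
                    mode: str = "within_run") -> SensitivityMap:
    """Sweep the FDR level and record where each pair loses significance."""
    grid = default_gamma_grid() if gamma_grid is None else np.asarray(
        gamma_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("gamma grid must be sorted strictly ascending")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("gamma grid must lie in (0, 1)")
    P = np.asarray(P, dtype=float)
    min_gamma = np.full(P.shape, np.inf)
    for g in grid[::-1]:  # descending: overwrite with ever-smaller levels
        res = threshold_matrix(P, g, mode=mode)
        min_gamma[res.reject] = g
    return SensitivityMap(gamma_grid=grid, min_gamma=min_gamma, mode=mode)


def false_positive_summary(results: list[FdrResult]) -> float:
    """Median percent-significant across null comparisons at one γ."""
    if not results:
        raise ValueError("no results to summarize")
    return float(np.median([r.percent_significant for r in results]))


def fwe_naive_rate(Z: np.ndarray, z_threshold: float = 2.0,
                   mode: str = "within_run") -> float:
    """Percent of tested pairs with |z| above a fixed cutoff (naïve FWE).

    The |z| > 2 rule is the uncorrected ≈0.05 familywise threshold whose
    false-positive inflation motivates FDR control.
    """
    if z_threshold <= 0:
        raise ValueError("z threshold must be positive")
    Z = np.asarray(Z, dtype=float)
    if mode == "within_run":
        vals = Z[np.tril_indices(Z.shape[0], k=-1)]
    elif mode == "cross_null":
        vals = Z.ravel()
    else:
        raise ValueError("mode must be 'within_run' or 'cross_null'")
    return float(100.0 * np.mean(np.abs(vals) > z_threshold))
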