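"""Autocorrelation-corrected variance, z-scores, and p-values.

Temporal autocorrelation inflates the variance of Pearson's correlation
between hemodynamic time series, so naïve z-scores are spuriously large.
Three per-pair variance estimators are provided:

``naive``
    V = (1 − R²)² / (T − 3): valid only for white signals.
``bartlett``
    V = (1 − R²)² / T̂ with effective degrees of freedom T̂ = T/⟨τ⟩, where
    τ is the autocorrelation time (sum of squared autocorrelations) and
    ⟨·⟩ averages over the mask. Accurate near the null when the
    autocorrelation is spatially homogeneous.
``xdf``
    The pairwise xDF estimator built from full (tapered, truncated) auto-
    and cross-correlation sequences, assuming only stationarity; floored
    elementwise at the naïve variance.

Two τ conventions coexist. The *single-sided* time
τ₁ = Σ_{i=0..M} (w_i ρ̂_i)², which for AR(1) equals 1/(1−φ²), is the
reported per-pixel map. The *two-sided* time τ₂ = 2τ₁ − 1 is the classical
Bartlett (1935) sum Σ_{i=−M..M} (w ρ̂)², which is the quantity that actually
calibrates Var(R) = ⟨τ₂⟩/T under the null for homogeneous autocorrelation
(for AR(1), (1+φ²)/(1−φ²)); the Bartlett variance estimator therefore uses
τ₂ by default. Both are available everywhere via ``two_sided``.

All correlation-sequence estimates are biased-normalized (divide by T),
Tukey-tapered with weights w_i = ½(1 + cos(πi/M)), and truncated at
M = round(2√T) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .connectivity import (CLIP, CorrelationResult, correlation_matrix,
                           cross_null_matrix, fisher_transform)
from .preprocess import NormalizedSeries, Parcellation

__all__ = [
    "AutocorrMap",
    "EffectiveDof",
    "VarianceMatrix",
    "StatMatrices",
    "default_max_lag",
    "tukey_weights",
    "sample_autocorr",
    "tapered_autocorr",
    "cross_corr_sequence",
    "autocorr_time",
    "autocorr_map",
    "bartlett_edof",
    "variance_naive",
    "variance_bartlett",
    "variance_xdf",
    "variance_xdf_pairs",
    "variance_xdf_matrix",
    "zscore",
    "pvalue",
    "ks_normality",
    "parcel_length_regression",
    "correlation_stats",
    "cross_null_stats",
]


# ---------------------------------------------------------------- sequences

def default_max_lag(n_frames: int) -> int:
    """Default truncation lag M = round(2√T)."""
    return int(round(2.0 * np.sqrt(n_frames)))


def tukey_weights(max_lag: int) -> np.ndarray:
    """Tukey taper w_i = ½(1 + cos(πi/M)) for i = 0..M (w_0=1, w_M=0)."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    i = np.arange(max_lag + 1)
    return 0.5 * (1.0 + np.cos(np.pi * i / max_lag))


def _fft_size(n: int) -> int:
    return 1 << int(np.ceil(np.log2(2 * n)))


def sample_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation ρ̂_i, i = 0..M, along the last axis.

    Biased normalization (divide by T) keeps the sequence positive
    semi-definite. Works on 1-D series or 2-D panels.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if max_lag >= T:
        raise ValueError(f"max_lag {max_lag} must be < series length {T}")
    xc = x - x.mean(axis=-1, keepdims=True)
    n = _fft_size(T)
    f = np.fft.rfft(xc, n)
    acov = np.fft.irfft(f * np.conj(f), n)[..., :max_lag + 1] / T
    return acov / acov[..., :1]


def tapered_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Tukey-tapered sample autocorrelation w_i ρ̂_i, i = 0..M."""
    return sample_autocorr(x, max_lag) * tukey_weights(max_lag)


def cross_corr_sequence(x: np.ndarray, y: np.ndarray, max_lag: int,
                        taper: bool = True) -> np.ndarray:
    """Cross-correlation ρ̂(x_t, y_{t+c}) for lags c = −M..M (length 2M+1).

    Row-paired for 2-D inputs. Index ``max_lag + c`` holds lag c; for x=y
    the sequence is symmetric with value 1 at c=0 (before tapering).
    """
    was_1d = np.ndim(x) == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    T = x.shape[-1]
    if max_lag >= T:
        raise ValueError("max_lag must be < series length")
    xc = x - x.mean(-1, keepdims=True)
    yc = y - y.mean(-1, keepdims=True)
    n = _fft_size(T)
    fx, fy = np.fft.rfft(xc, n), np.fft.rfft(yc, n)
    full = np.fft.irfft(np.conj(fx) * fy, n)
    pos = full[..., :max_lag + 1]     # lags 0..M: Σ x_t y_{t+c}
    neg = full[..., n - max_lag:]     # index n−k holds lag −k: lags −M..−1
    seq = np.concatenate([neg, pos], axis=-1) / T
    norm = np.sqrt((xc ** 2).mean(-1) * (yc ** 2).mean(-1))
    seq = seq / norm[..., None]
    if taper:
        w = tukey_weights(max_lag)
        seq = seq * np.concatenate([w[1:][::-1], w])
    return seq[0] if was_1d else seq


# ------------------------------------------------------- autocorrelation time

def autocorr_time(x: np.ndarray, max_lag: int,
                  two_sided: bool = False) -> np.ndarray | float:
    """Autocorrelation time τ = Σ_{i=0..M} (w_i ρ̂_i)² (per row for panels).

    ``two_sided=True`` returns the classical Bartlett sum over lags
    −M..M, i.e. 2τ − 1.
    """
    rho = tapered_autocorr(x, max_lag)
    tau = (rho ** 2).sum(axis=-1)
    if two_sided:
        tau = 2.0 * tau - 1.0
    return float(tau) if np.ndim(tau) == 0 else tau


@dataclass(frozen=True)
class AutocorrMap:
    """Per-pixel (or per-parcel) autocorrelation times for one run."""

    tau: np.ndarray
    taper_max_lag: int
    mean_tau: float
    T: int
    two_sided: bool = False

    def __post_init__(self) -> None:
        if np.any(self.tau < 1.0 - 1e-9):
            raise ValueError("autocorrelation times below 1 (lag-0 term)")


def autocorr_map(series: NormalizedSeries, max_lag: int | None = None,
                 two_sided: bool = False) -> AutocorrMap:
    """Estimate τ for every row of a normalized series."""
    M = default_max_lag(series.n_frames) if max_lag is None else int(max_lag)
    tau = autocorr_time(series.data, M, two_sided=two_sided)
    tau = np.maximum(np.atleast_1d(tau), 1.0)  # lag-0 contributes exactly 1
    return AutocorrMap(tau=tau, taper_max_lag=M, mean_tau=float(tau.mean()),
                       T=series.n_frames, two_sided=two_sided)


@dataclass(frozen=True)
class EffectiveDof:
    """Effective degrees of freedom T̂ = T / ⟨τ⟩."""

    T_hat: float
    T: int
    mean_tau: float

    def __post_init__(self) -> None:
        if not 0 < self.T_hat <= self.T + 1e-9:
            raise ValueError("effective DOF must lie in (0, T]")


def bartlett_edof(acmap: AutocorrMap, summary: str = "mean") -> EffectiveDof:
    """T̂ = T / ⟨τ⟩ with ⟨·⟩ the arithmetic mean (or median) over the mask."""
    if summary == "mean":
        avg = float(np.mean(acmap.tau))
    elif summary == "median":
        avg = float(np.median(acmap.tau))
    else:
        raise ValueError("summary must be 'mean' or 'median'")
    if avg < 1.0:
        raise ValueError("mean autocorrelation time below 1")
    return EffectiveDof(T_hat=acmap.T / avg, T=acmap.T, mean_tau=avg)


# ------------------------------------------------------------------ variance

def variance_naive(r: np.ndarray | float, T: int) -> np.ndarray | float:
    """V(R) = (1 − R²)² / (T − 3), valid in the absence of autocorrelation."""
    if T <= 3:
        raise ValueError("need T > 3 frames")
    r = np.asarray(r, dtype=float)
    v = (1.0 - r ** 2) ** 2 / (T - 3)
    return float(v) if v.ndim == 0 else v


def variance_bartlett(r: np.ndarray | float,
                      edof: EffectiveDof) -> np.ndarray | float:
    """V(R) = (1 − R²)² / T̂ with Bartlett effective degrees of freedom."""
    r = np.asarray(r, dtype=float)
    v = (1.0 - r ** 2) ** 2 / edof.T_hat
    return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class VarianceMatrix:
    """Per-pair variance of R with its estimator label."""

    V: np.ndarray
    estimator: str
    floor_applied: np.ndarray | None = None  # xdf only
    edof: EffectiveDof | None = None


def _xdf_from_sequences(r0, ax, ay, cpos, cneg, T, cross_term):
    """Evaluate the xDF variance from tapered correlation sequences.

    ``ax``/``ay``: tapered autocorrelations at lags 1..M for each member of
    the pair; ``cpos``/``cneg``: tapered cross-correlations at lags
    +1..+M and −1..−M. Shapes must broadcast against ``r0 [..., None]``.
    Sums are weighted by (T − 2 − k).
    """
    M = ax.shape[-1]
    u = (T - 2.0) - np.arange(1, M + 1)
    if cross_term == "squares_product":
        ct = cpos ** 2 * cneg ** 2
    elif cross_term == "lag_product":
        ct = cpos * cneg
    else:
        raise ValueError("cross_term must be 'squares_product' or 'lag_product'")
    s_rho2 = ((ax ** 2 + ay ** 2 + ct) * u).sum(-1)
    s_mixed = ((ax + ay) * (cpos + cneg) * u).sum(-1)
    s_null = ((ax * ay + cpos * cneg) * u).sum(-1)
    v = ((T - 2.0) * (1.0 - r0 ** 2) ** 2
         + r0 ** 2 * s_rho2
         - 2.0 * r0 * s_mixed
         + 2.0 * s_null) / T ** 2
    return v


def _apply_floor(v_raw: np.ndarray, r0: np.ndarray, T: int):
    # degenerate pairs (|r|≈1) get the clipped naive floor so V stays > 0
    floor = variance_naive(np.clip(r0, -1 + CLIP, 1 - CLIP), T)
    flag = v_raw < floor
    return np.maximum(v_raw, floor), flag


def variance_xdf_pairs(x: np.ndarray, y: np.ndarray,
                       max_lag: int | None = None,
                       cross_term: str = "squares_product"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """xDF variance for row-paired panels (row i of x with row i of y).

    Returns ``(V, floor_applied)``; V is floored elementwise at the naïve
    variance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("paired panels must have the same shape")
    T = x.shape[-1]
    M = default_max_lag(T) if max_lag is None else int(max_lag)
    if M >= T:
        raise ValueError("max_lag must be < series length")
    xs = (x - x.mean(-1, keepdims=True)) / x.std(-1, keepdims=True)
    ys = (y - y.mean(-1, keepdims=True)) / y.std(-1, keepdims=True)
    r0 = (xs * ys).mean(-1)
    ax = tapered_autocorr(x, M)[..., 1:]
    ay = tapered_autocorr(y, M)[..., 1:]
    c = cross_corr_sequence(x, y, M, taper=True)
    cpos = c[..., M + 1:]
    cneg = c[..., :M][..., ::-1]  # lags −1..−M
    v = _xdf_from_sequences(r0, ax, ay, cpos, cneg, T, cross_term)
    return _apply_floor(v, r0, T)


def variance_xdf(series_p: np.ndarray, series_q: np.ndarray,
                 max_lag: int | None = None,
                 cross_term: str = "squares_product") -> tuple[float, bool]:
    """xDF variance of the correlation of one pair of series."""
    v, flag = variance_xdf_pairs(series_p[None], series_q[None],
                                 max_lag=max_lag, cross_term=cross_term)
    return float(v[0]), bool(flag[0])


def variance_xdf_matrix(series_a: NormalizedSeries,
                        series_b: NormalizedSeries | None = None,
                        max_lag: int | None = None,
                        cross_term: str = "squares_product",
                        chunk: int = 64) -> VarianceMatrix:
    """xDF variance for every pair of rows (full matrix, chunked over rows).

    With one argument, all within-run pairs (symmetric matrix); with two,
    the Pa×Pb cross-run pairs. The computation is pure per pair and is
    chunked to bound the Pa×Pb×(2M+1) cross-correlation workspace.
    """
    sym = series_b is None
    b = series_a if sym else series_b
    if series_a.n_frames != b.n_frames:
        raise ValueError("series must have equal frame counts")
    T = series_a.n_frames
    M = default_max_lag(T) if max_lag is None else int(max_lag)
    if M >= T:
        raise ValueError("max_lag must be < series length")
    w = tukey_weights(M)
    A = series_a.data
    B = b.data
    ax = tapered_autocorr(A, M)[:, 1:]
    ay = ax if sym else tapered_autocorr(B, M)[:, 1:]
    r0 = (A @ B.T) / T
    n = _fft_size(T)
    fa = np.fft.rfft(A - A.mean(-1, keepdims=True), n)
    fb = fa if sym else np.fft.rfft(B - B.mean(-1, keepdims=True), n)
    sda = np.sqrt((A ** 2).mean(-1) - A.mean(-1) ** 2)
    sdb = sda if sym else np.sqrt((B ** 2).mean(-1) - B.mean(-1) ** 2)
    V = np.empty_like(r0)
    flag = np.empty(r0.shape, dtype=bool)
    for lo in range(0, A.shape[0], chunk):
        hi = min(lo + chunk, A.shape[0])
        spec = np.conj(fa[lo:hi, None, :]) * fb[None, :, :]
        full = np.fft.irfft(spec, n)
        cpos = full[..., 1:M + 1] / T * w[1:]
        cneg = full[..., n - M:][..., ::-1] / T * w[1:]
        norm = (sda[lo:hi, None] * sdb[None, :])[..., None]
        cpos, cneg = cpos / norm, cneg / norm
        v = _xdf_from_sequences(r0[lo:hi], ax[lo:hi, None, :], ay[None, :, :],
                                cpos, cneg, T, cross_term)
        V[lo:hi], flag[lo:hi] = _apply_floor(v, r0[lo:hi], T)
    if sym:
        V = (V + V.T) / 2.0
        flag = flag | flag.T
    return VarianceMatrix(V=V, estimator="xdf", floor_applied=flag)


# ------------------------------------------------------------- z and p values

def zscore(F: np.ndarray | float, r: np.ndarray | float,
           V: np.ndarray | float) -> np.ndarray | float:
    """Z = F · (1 − R²) / √V(R).

    With the naïve variance this reduces exactly to √(T−3) · F.
    """
    F, r, V = (np.asarray(a, dtype=float) for a in (F, r, V))
    if np.any(V <= 0):
        raise ValueError("variance must be positive")
    z = F * (1.0 - r ** 2) / np.sqrt(V)
    return float(z) if z.ndim == 0 else z


def pvalue(z: np.ndarray | float) -> np.ndarray | float:
    """Two-tailed normal p-value, p = 2(1 − Φ(|z|)), clamped above zero."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    p = np.maximum(2.0 * _sps.norm.sf(np.abs(z)), np.finfo(float).tiny)
    return float(p) if p.ndim == 0 else p


def ks_normality(z_values: np.ndarray) -> float:
    """One-sample Kolmogorov–Smirnov statistic against N(0, 1)."""
    z = np.ravel(np.asarray(z_values, dtype=float))
    if z.size < 50:
        raise ValueError("need at least 50 z-values for the KS statistic")
    return float(_sps.kstest(z, "norm").statistic)


def parcel_length_regression(acmap: AutocorrMap,
                             parcellation: Parcellation
                             ) -> tuple[float, float]:
    """OLS of parcel-level τ on characteristic length √area (pixels).

    Returns ``(slope, r)``; the map must already be parcel-level (one τ
    per parcel, ordered like sorted parcel ids).
    """
    if parcellation.n_parcels < 3:
        raise ValueError("need at least 3 parcels for the regression")
    if acmap.tau.size != parcellation.n_parcels:
        raise ValueError("autocorrelation map is not parcel-level")
    length = np.sqrt(parcellation.areas.astype(float))
    if np.allclose(acmap.tau, acmap.tau[0]):
        return 0.0, 0.0
    res = _sps.linregress(length, acmap.tau)
    return float(res.slope), float(res.rvalue)


# --------------------------------------------------------------- orchestration

@dataclass(frozen=True)
class StatMatrices:
    """R, F, V, Z, P for one run (or one null cross-run pair)."""

    corr: CorrelationResult
    variance: VarianceMatrix
    Z: np.ndarray
    P: np.ndarray

    @property
    def estimator(self) -> str:
        return self.variance.estimator


def _finish(corr: CorrelationResult, vmat: VarianceMatrix) -> StatMatrices:
    Z = zscore(corr.F, np.clip(corr.R, -1 + CLIP, 1 - CLIP), vmat.V)
    return StatMatrices(corr=corr, variance=vmat, Z=Z, P=pvalue(Z))


def correlation_stats(series: NormalizedSeries, estimator: str = "bartlett",
                      max_lag: int | None = None,
                      bartlett_two_sided: bool = True,
                      cross_term: str = "squares_product") -> StatMatrices:
    """Within-run correlation matrix with variance-corrected z and p values.

    ``bartlett_two_sided`` selects the classical two-sided autocorrelation
    time for the effective DOF (the calibrated default); the printed
    single-sided form is available for comparison.
    """
    corr = correlation_matrix(series)
    T = series.n_frames
    Rc = np.clip(corr.R, -1 + CLIP, 1 - CLIP)
    if estimator == "naive":
        vmat = VarianceMatrix(V=variance_naive(Rc, T), estimator="naive")
    elif estimator == "bartlett":
        acmap = autocorr_map(series, max_lag, two_sided=bartlett_two_sided)
        edof = bartlett_edof(acmap)
        vmat = VarianceMatrix(V=variance_bartlett(Rc, edof),
                              estimator="bartlett", edof=edof)
    elif estimator == "xdf":
        vmat = variance_xdf_matrix(series, max_lag=max_lag,
                                   cross_term=cross_term)
    else:
        raise ValueError("estimator must be 'naive', 'bartlett', or 'xdf'")
    return _finish(corr, vmat)


def cross_null_stats(series_a: NormalizedSeries, series_b: NormalizedSeries,
                     estimator: str = "bartlett",
                     max_lag: int | None = None,
                     bartlett_two_sided: bool = True,
                     cross_term: str = "squares_product") -> StatMatrices:
    """Cross-run (null) correlation matrix with corrected z and p values.

    For the Bartlett estimator the effective DOF uses the global average
    autocorrelation time pooled over the pixels of both runs.
    """
    corr = cross_null_matrix(series_a, series_b)
    T = corr.n_frames
    Rc = np.clip(corr.R, -1 + CLIP, 1 - CLIP)
    if estimator == "naive":
        vmat = VarianceMatrix(V=variance_naive(Rc, T), estimator="naive")
    elif estimator == "bartlett":
        M = default_max_lag(T) if max_lag is None else int(max_lag)
        tau = np.concatenate([
            np.atleast_1d(autocorr_time(s.data, M, two_sided=bartlett_two_sided))
            for s in (series_a, series_b)])
        acmap = AutocorrMap(tau=np.maximum(tau, 1.0), taper_max_lag=M,
                            mean_tau=float(np.maximum(tau, 1.0).mean()), T=T,
                            two_sided=bartlett_two_sided)
        edof = bartlett_edof(acmap)
        vmat = VarianceMatrix(V=variance_bartlett(Rc, edof),
                              estimator="bartlett", edof=edof)
    elif estimator == "xdf":
        vmat = variance_xdf_matrix(series_a, series_b, max_lag=max_lag,
                                   cross_term=cross_term)
    else:
        raise ValueError("estimator must be 'naive', 'bartlett', or 'xdf'")
    return _finish(corr, vmat)
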