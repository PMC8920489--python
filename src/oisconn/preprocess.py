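"""Reduction of raw hemodynamic movies to the normalized series H(p, t).

The statistics downstream (correlation matrices, autocorrelation-corrected
variances, FDR thresholding) all operate on a masked pixel-by-time matrix
that has been spatially smoothed, bandpass filtered and downsampled,
global-signal regressed, and normalized to zero mean / unit SD per pixel.
This module implements that reduction and the bookkeeping (brain mask,
fixed pixel ordering, provenance) that keeps every stage aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy.signal import fftconvolve

__all__ = [
    "BrainMask",
    "Parcellation",
    "RawSeries",
    "NormalizedSeries",
    "spatial_smooth",
    "temporal_filter_downsample",
    "global_signal_regress",
    "normalize",
    "parcel_average",
    "concatenate_runs",
    "gaussian_kernel",
]


class PipelineOrderError(RuntimeError):
    """A preprocessing step was applied twice or out of order."""


@dataclass(frozen=True)
class BrainMask:
    """Binary brain mask with the fixed row-major pixel ordering.

    ``pixel_index`` maps row *i* of every pixel-by-time matrix to grid
    coordinates ``(row, col)``; the order is row-major over the mask and is
    fixed at construction so that series, correlation matrices, and maps
    painted back onto the grid always agree.
    """

    image: np.ndarray
    pixel_index: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=bool)
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "pixel_index", np.asarray(self.pixel_index))
        if self.n_pixels < 2:
            raise ValueError("brain mask must contain at least 2 pixels")

    @classmethod
    def from_image(cls, image: np.ndarray) -> "BrainMask":
        image = np.asarray(image, dtype=bool)
        idx = np.argwhere(image)  # row-major order
        return cls(image=image, pixel_index=idx)

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_index.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.image.shape)

    def extract(self, frames: np.ndarray) -> np.ndarray:
        """Flatten a (T, rows, cols) stack to (n_pixels, T) in mask order."""
        frames = np.asarray(frames)
        r, c = self.pixel_index[:, 0], self.pixel_index[:, 1]
        return frames[:, r, c].T.copy()

    def paint(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Paint a per-pixel vector back onto the grid (``fill`` outside)."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.n_pixels:
            raise ValueError("value vector does not match mask pixel count")
        out = np.full(self.shape, fill, dtype=float)
        out[self.pixel_index[:, 0], self.pixel_index[:, 1]] = values
        return out

    def __eq__(self, other: object) -> bool:  # value equality for run checks
        return (
            isinstance(other, BrainMask)
            and self.image.shape == other.image.shape
            and bool(np.array_equal(self.image, other.image))
        )


@dataclass(frozen=True)
class Parcellation:
    """Integer label image assigning masked pixels to regions (0 = none)."""

    labels: np.ndarray
    parcel_ids: np.ndarray
    areas: np.ndarray

    @classmethod
    def from_labels(cls, labels: np.ndarray, mask: BrainMask) -> "Parcellation":
        labels = np.asarray(labels, dtype=int)
        if labels.shape != mask.shape:
            raise ValueError("label image shape does not match mask")
        if np.any(labels[~mask.image] != 0):
            raise ValueError("parcel labels present outside the brain mask")
        ids = np.unique(labels[labels > 0])
        if ids.size == 0:
            raise ValueError("parcellation contains no labeled pixels")
        areas = np.array([(labels == i).sum() for i in ids])
        return cls(labels=labels, parcel_ids=ids, areas=areas)

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_ids.size)

    def member_rows(self, mask: BrainMask, parcel_id: int) -> np.ndarray:
        """Row indices (in mask order) of the pixels in one parcel."""
        lab = self.labels[mask.pixel_index[:, 0], mask.pixel_index[:, 1]]
        return np.flatnonzero(lab == parcel_id)

    def paint(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Paint per-parcel values onto the label image."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.n_parcels:
            raise ValueError("value vector does not match parcel count")
        out = np.full(self.labels.shape, fill, dtype=float)
        for pid, v in zip(self.parcel_ids, values):
            out[self.labels == pid] = v
        return out


_STAGE_ORDER = ("spatial_smooth", "temporal_filter", "gsr", "normalize")


def _check_step(provenance: tuple[str, ...], step: str) -> None:
    """Reject re-running a stage or running stages out of pipeline order."""
    applied = [p.split(":")[0] for p in provenance]
    if step in applied:
        raise PipelineOrderError(f"step '{step}' already applied: {provenance}")
    rank = _STAGE_ORDER.index(step)
    later = [s for s in applied
             if s in _STAGE_ORDER and _STAGE_ORDER.index(s) > rank]
    if later:
        raise PipelineOrderError(
            f"step '{step}' must precede {later}: {provenance}")


@dataclass(frozen=True)
class RawSeries:
    """Masked pixel-by-time matrix of hemodynamic values (e.g. ΔHbT)."""

    data: np.ndarray
    fs: float
    mask: BrainMask
    run_id: str = "run"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("series data must be 2-D (pixels x time)")
        if data.shape[0] != self.mask.n_pixels:
            raise ValueError(
                f"series has {data.shape[0]} rows but mask has "
                f"{self.mask.n_pixels} pixels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("series contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[1])

    def to_frames(self, fill: float = 0.0) -> np.ndarray:
        """Unflatten to a (T, rows, cols) stack (``fill`` outside the mask)."""
        out = np.full((self.n_frames,) + self.mask.shape, fill, dtype=float)
        r, c = self.mask.pixel_index[:, 0], self.mask.pixel_index[:, 1]
        out[:, r, c] = self.data.T
        return out


@dataclass(frozen=True)
class NormalizedSeries:
    """Normalized series H(p, t): zero mean, unit SD per pixel.

    ``run_boundaries`` records frame offsets of concatenated runs (each
    segment keeps its own normalization). ``parcel_ids`` is set when rows
    are parcel averages rather than single pixels.
    """

    data: np.ndarray
    fs: float
    mask: BrainMask
    provenance: tuple[str, ...] = ()
    run_boundaries: tuple[int, ...] = (0,)
    parcel_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.parcel_ids is None and data.shape[0] != self.mask.n_pixels:
            raise ValueError("row count does not match mask pixel count")
        # Per-segment normalization means the whole row is only approximately
        # unit SD after concatenation; validate per declared segment instead.
        bounds = list(self.run_boundaries) + [data.shape[1]]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = data[:, a:b]
            if not (np.all(np.abs(seg.mean(axis=1)) < 1e-8)
                    and np.all(np.abs(seg.std(axis=1) - 1.0) < 1e-6)):
                raise ValueError("segment rows are not zero-mean/unit-SD")

    @property
    def n_rows(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[1])


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Truncated 2-D Gaussian kernel, normalized to sum 1."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ax = np.arange(size) - size // 2
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def spatial_smooth(raw: RawSeries, kernel_size: int = 5,
                   sigma: float = 1.0) -> RawSeries:
    """Frame-wise Gaussian smoothing restricted to the brain mask.

    The kernel is renormalized over in-mask support, so pixels outside the
    mask contribute nothing and the weights at mask edges re-sum to one
    (constant frames are preserved everywhere).
    """
    _check_step(raw.provenance, "spatial_smooth")
    k = gaussian_kernel(kernel_size, sigma)
    frames = raw.to_frames(fill=0.0)
    m = raw.mask.image.astype(float)
    num = fftconvolve(frames * m[None], k[None], mode="same", axes=(1, 2))
    den = fftconvolve(m, k, mode="same")
    r, c = raw.mask.pixel_index[:, 0], raw.mask.pixel_index[:, 1]
    smoothed = (num[:, r, c] / den[r, c]).T
    prov = raw.provenance + (f"spatial_smooth:{kernel_size}x{kernel_size},sigma={sigma}",)
    return replace(raw, data=smoothed, provenance=prov)


def temporal_filter_downsample(raw: RawSeries, low: float = 0.01,
                               high: float = 0.1,
                               target_fs: float = 1.0) -> RawSeries:
    """Zero-phase Butterworth bandpass, then decimation to ``target_fs``.

    The bandpass is a 4th-order Butterworth applied forward and backward
    (``sosfiltfilt``), then every (fs/target_fs)-th sample is kept; the
    0.1 Hz low-pass edge already prevents aliasing at 1 Hz.
    """
    _check_step(raw.provenance, "temporal_filter")
    nyq = raw.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq})")
    if target_fs > raw.fs:
        raise ValueError("target_fs cannot exceed the sampling rate")
    factor = raw.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs/target_fs={factor} is not an integer")
    factor = int(round(factor))
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=raw.fs,
                         output="sos")
    filtered = _signal.sosfiltfilt(sos, raw.data, axis=1)
    decimated = filtered[:, ::factor]
    prov = raw.provenance + (
        f"temporal_filter:band={low}-{high}Hz,target_fs={target_fs}",)
    return replace(raw, data=np.ascontiguousarray(decimated), fs=target_fs,
                   provenance=prov)


def global_signal_regress(raw: RawSeries) -> RawSeries:
    """Regress the mask-mean time course out of every pixel (with intercept).

    Residuals are orthogonal to the global signal and have zero mean.
    """
    _check_step(raw.provenance, "gsr")
    if raw.n_pixels < 2:
        raise ValueError("global signal regression needs >= 2 pixels")
    g = raw.data.mean(axis=0)
    gc = g - g.mean()
    var_g = float(gc @ gc)
    if var_g < 1e-15 * raw.n_frames:
        raise ValueError("global signal has (near-)zero variance")
    beta = (raw.data @ gc) / var_g
    resid = raw.data - raw.data.mean(axis=1, keepdims=True) - np.outer(beta, gc)
    return replace(raw, data=resid, provenance=raw.provenance + ("gsr",))


def normalize(raw: RawSeries) -> NormalizedSeries:
    """Normalize each pixel series to zero mean and unit SD."""
    _check_step(raw.provenance, "normalize")
    sd = raw.data.std(axis=1)
    bad = np.flatnonzero(sd <= 1e-12 * np.abs(raw.data).max())
    if bad.size:
        raise ValueError(
            f"{bad.size} pixel(s) have zero variance (rows {bad.tolist()}); "
            "drop them from the mask before normalizing")
    data = (raw.data - raw.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return NormalizedSeries(data=data, fs=raw.fs, mask=raw.mask,
                            provenance=raw.provenance + ("normalize",))


def parcel_average(series: NormalizedSeries,
                   parcellation: Parcellation) -> NormalizedSeries:
    """Average member-pixel series per parcel, then re-normalize each row.

    Rows of the result follow sorted parcel ids.
    """
    if series.parcel_ids is not None:
        raise PipelineOrderError("series is already parcel-averaged")
    rows = []
    for pid in parcellation.parcel_ids:
        members = parcellation.member_rows(series.mask, int(pid))
        if members.size == 0:
            raise ValueError(f"parcel {pid} has no member pixels in the mask")
        rows.append(series.data[members].mean(axis=0))
    data = np.asarray(rows)
    sd = data.std(axis=1)
    if np.any(sd <= 0):
        raise ValueError("a parcel-average series has zero variance")
    data = (data - data.mean(axis=1, keepdims=True)) / sd[:, None]
    return NormalizedSeries(
        data=data, fs=series.fs, mask=series.mask,
        provenance=series.provenance + ("parcel_average",),
        parcel_ids=tuple(int(i) for i in parcellation.parcel_ids))


def concatenate_runs(runs: list[NormalizedSeries]) -> NormalizedSeries:
    """Concatenate runs time-wise, keeping each run's own normalization."""
    if not runs:
        raise ValueError("no runs to concatenate")
    if len(runs) == 1:
        return runs[0]
    first = runs[0]
    for r in runs[1:]:
        if r.mask != first.mask:
            raise ValueError("runs have mismatched masks")
        if r.fs != first.fs:
            raise ValueError("runs have mismatched sampling rates")
        if r.parcel_ids != first.parcel_ids:
            raise ValueError("runs have mismatched row definitions")
    boundaries, offset = [], 0
    for r in runs:
        boundaries.extend(b + offset for b in r.run_boundaries)
        offset += r.n_frames
    data = np.concatenate([r.data for r in runs], axis=1)
    prov = first.provenance + (f"concatenate:{len(runs)}runs",)
    return NormalizedSeries(data=data, fs=first.fs, mask=first.mask,
                            provenance=prov,
                            run_boundaries=tuple(boundaries),
                            parcel_ids=first.parcel_ids)
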