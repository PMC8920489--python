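"""Pearson correlation matrices, Fisher transforms, and seed maps.

Within-run functional connectivity is the P×P Pearson matrix
R(p,q) = ρ(H(p,t), H(q,t)); null-calibration data come from correlating
every pixel of one run against every pixel of an independent run, where
all true correlations are zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import BrainMask, NormalizedSeries

__all__ = [
    "CorrelationResult",
    "correlation_matrix",
    "cross_null_matrix",
    "fisher_transform",
    "seed_map",
    "CLIP",
]

#: correlations are clipped to ±(1 − CLIP) before arctanh so F stays finite
CLIP = 1e-7


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation matrix R with its Fisher transform F = arctanh(R)."""

    R: np.ndarray
    F: np.ndarray
    n_frames: int
    mode: str  # "within_run" | "cross_null"
    mask: BrainMask | None = None
    parcel_ids: tuple[int, ...] | None = None

    @property
    def n_rows(self) -> int:
        return int(self.R.shape[0])


def fisher_transform(r: np.ndarray | float) -> np.ndarray | float:
    """arctanh with |r| clipped to 1−1e−7 so perfect correlations stay finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -1 + CLIP, 1 - CLIP))
    return out if out.ndim else float(out)


def correlation_matrix(series: NormalizedSeries) -> CorrelationResult:
    """Full within-run Pearson matrix of the normalized series.

    Rows of H are zero-mean/unit-SD (per segment for concatenated runs,
    which still gives whole-row mean 0 and SD 1), so R = H Hᵀ / T.
    """
    if series.n_frames < 5:
        raise ValueError("need at least 5 frames for a correlation matrix")
    H = series.data
    R = (H @ H.T) / series.n_frames
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    if np.any(np.abs(R - np.eye(len(R))) >= 1 - CLIP):
        warnings.warn("duplicate (|r|=1) off-diagonal pixel pairs present",
                      stacklevel=2)
    return CorrelationResult(R=R, F=fisher_transform(R),
                             n_frames=series.n_frames, mode="within_run",
                             mask=series.mask, parcel_ids=series.parcel_ids)


def cross_null_matrix(series_a: NormalizedSeries,
                      series_b: NormalizedSeries) -> CorrelationResult:
    """Pa×Pb matrix of correlations between two independent runs.

    Not symmetric in general and has no unit diagonal; with independent
    sources every true correlation is zero, giving null-hypothesis data.
    """
    if series_a.n_frames != series_b.n_frames:
        raise ValueError("cross-null series must have equal frame counts")
    if series_a.data is series_b.data or (
            series_a.data.shape == series_b.data.shape
            and np.shares_memory(series_a.data, series_b.data)):
        warnings.warn("cross_null_matrix called with a series against itself",
                      stacklevel=2)
    R = (series_a.data @ series_b.data.T) / series_a.n_frames
    R = np.clip(R, -1.0, 1.0)
    return CorrelationResult(R=R, F=fisher_transform(R),
                             n_frames=series_a.n_frames, mode="cross_null",
                             mask=series_a.mask)


def seed_map(corr: CorrelationResult, seed_index: int) -> np.ndarray:
    """Paint one row of the correlation matrix back onto the mask grid.

    Unmasked pixels are NaN. For parcel-level results the value of each
    parcel is painted over its pixels via the mask is not available here;
    use ``Parcellation.paint`` for that case.
    """
    if not 0 <= seed_index < corr.n_rows:
        raise IndexError("seed index out of range")
    if corr.mask is None or corr.parcel_ids is not None:
        raise ValueError("seed_map needs a pixel-level result with a mask")
    return corr.mask.paint(corr.R[seed_index])
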