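"""Synthetic widefield hemodynamic data with known ground truth.

Emulates the regime of bandpassed, 1-Hz mouse optical intrinsic signal
runs: per-pixel temporal autocorrelation (stationary AR(1), τ of a few
seconds), spatial smoothness on a ~5-pixel Gaussian scale, and planted
block networks of correlated/anticorrelated pixels — so that every
downstream statistic can be checked against known truth.

Construction: ``n_networks`` latent AR(1) network signals are mixed by the
Cholesky factor of the latent network correlation matrix; each masked
pixel is then sqrt(w)·(its network signal) + sqrt(1−w)·(an independent
AR(1) idiosyncratic series), which realizes a within-network pixel
correlation of ``w`` and a between-network pixel correlation of
``between_network_corr`` exactly at the population level. Optional
spatial smoothing is applied afterwards inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .preprocess import BrainMask, Parcellation, RawSeries, spatial_smooth

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_ar1_panel",
    "generate_dataset",
    "generate_null_pair",
    "elliptical_mask",
    "ar1_tau",
]


def ar1_tau(phi: np.ndarray | float) -> np.ndarray | float:
    """Analytic single-sided autocorrelation time of AR(1): Σφ^{2i} = 1/(1−φ²)."""
    return 1.0 / (1.0 - np.asarray(phi, dtype=float) ** 2)


def generate_ar1_panel(n_pixels: int, n_frames: int,
                       phi: float | np.ndarray,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Independent stationary AR(1) rows with unit marginal variance.

    x[t] = φ x[t−1] + sqrt(1−φ²) ε[t], started from the stationary
    distribution, so every sample has variance 1 and lag-k autocorrelation
    φ^k from the first frame on. ``phi`` may be a scalar or a per-row
    array. Deterministic given the seed.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    phi_arr = np.asarray(phi, dtype=float)
    if not np.all(np.abs(phi_arr) < 1):
        raise ValueError("AR(1) coefficients must satisfy |phi| < 1 "
                         "(stationarity)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x0 = rng.standard_normal(n_pixels)
    e = rng.standard_normal((n_pixels, n_frames))
    if phi_arr.ndim == 0:
        p = float(phi_arr)
        out, _ = lfilter([1.0], [1.0, -p], np.sqrt(1.0 - p ** 2) * e,
                         axis=-1, zi=(p * x0)[:, None])
        return out
    if phi_arr.shape != (n_pixels,):
        raise ValueError("per-pixel phi must have one value per row")
    innov = np.sqrt(1.0 - phi_arr[:, None] ** 2) * e
    out = np.empty_like(innov)
    prev = x0
    for t in range(n_frames):  # vectorized over rows; T iterations only
        prev = phi_arr * prev + innov[:, t]
        out[:, t] = prev
    return out


def elliptical_mask(grid_shape: tuple[int, int],
                    mask_fraction: float) -> BrainMask:
    """Centered elliptical mask covering ≈``mask_fraction`` of the grid.

    Echoes the roughly elliptical dorsal-brain field of view of widefield
    mouse imaging.
    """
    if not 0 < mask_fraction <= 1:
        raise ValueError("mask_fraction must be in (0, 1]")
    h, w = grid_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    # ellipse semi-axes proportional to the grid; scale so the covered area
    # matches the requested fraction (π ab / (hw) = fraction)
    s = np.sqrt(mask_fraction * h * w / (np.pi * (h / 2) * (w / 2)))
    a, b = s * h / 2, s * w / 2
    img = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    if img.sum() < 2:
        raise ValueError("mask_fraction too small for this grid")
    return BrainMask.from_image(img)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic run.

    Defaults emulate a 5-min run at 1 Hz after 0.01–0.1 Hz bandpass:
    T=300 frames, AR(1) φ=0.75 (τ = 1/(1−φ²) ≈ 2.3 s, inside the 2–3.5 s
    range typical of this kind of data), two planted networks with strong
    within-network correlation and a negative between-network correlation,
    and Gaussian spatial smoothness of 1 pixel SD.
    """

    grid_shape: tuple[int, int] = (16, 16)
    mask_fraction: float = 0.6
    n_frames: int = 300
    ar_coeff: float | np.ndarray = 0.75
    n_networks: int = 2
    within_network_corr: float = 0.7
    between_network_corr: float = -0.3
    spatial_sigma: float = 1.0
    fs: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if not abs(self.within_network_corr) < 1:
            raise ValueError("|within_network_corr| must be < 1")
        if not abs(self.between_network_corr) < 1:
            raise ValueError("|between_network_corr| must be < 1")
        if self.n_networks < 1:
            raise ValueError("need at least one network")
        if not np.all(np.abs(np.asarray(self.ar_coeff)) < 1):
            raise ValueError("|ar_coeff| must be < 1 (stationarity)")
        self.latent_corr()  # PSD check at construction

    def latent_corr(self) -> np.ndarray:
        """Latent network-signal correlation matrix (unit diagonal).

        Off-diagonal entries are between/within so that pixel pairs across
        networks correlate at ``between_network_corr`` after the sqrt(w)
        loading. Must be positive semi-definite.
        """
        n, w, b = self.n_networks, self.within_network_corr, self.between_network_corr
        if n == 1:
            return np.ones((1, 1))
        if w <= 0:
            if b != 0:
                raise ValueError(
                    "between_network_corr must be 0 when within_network_corr <= 0")
            return np.eye(n)
        off = b / w
        C = np.full((n, n), off)
        np.fill_diagonal(C, 1.0)
        evals = np.linalg.eigvalsh(C)
        if evals.min() < -1e-10:
            bad = [(i, j) for i in range(n) for j in range(i)]
            raise ValueError(
                "implied block correlation matrix is not positive "
                f"semi-definite (min eigenvalue {evals.min():.3g}); "
                f"offending off-diagonal entries {bad} = {off:.3g} "
                f"(between/within = {b}/{w})")
        return C

    def truth_corr(self) -> np.ndarray:
        """Block-level ground-truth pixel correlation targets (unit diagonal
        meaning: diagonal blocks are within-network pairs at
        ``within_network_corr``; read off-diagonals as the between-network
        pixel-pair correlation)."""
        n = self.n_networks
        C = np.full((n, n), self.between_network_corr)
        np.fill_diagonal(C, 1.0)
        return C


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated run plus its ground truth."""

    raw: RawSeries
    mask: BrainMask
    parcellation: Parcellation
    truth_corr: np.ndarray
    truth_tau: np.ndarray
    config: SyntheticConfig
    seed: int

    @property
    def series(self) -> np.ndarray:
        return self.raw.data

    def network_of_rows(self) -> np.ndarray:
        """Planted network label of every masked-pixel row (mask order)."""
        lab = self.parcellation.labels
        return lab[self.mask.pixel_index[:, 0], self.mask.pixel_index[:, 1]]


def _assign_networks(mask: BrainMask, n_networks: int) -> np.ndarray:
    """Split masked pixels into n contiguous row-major stripes."""
    n_pix = mask.n_pixels
    if n_networks > n_pix:
        raise ValueError("more networks than masked pixels")
    return 1 + (np.arange(n_pix) * n_networks) // n_pix


def generate_dataset(config: SyntheticConfig,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate one synthetic run realizing the configured network structure.

    ``seed`` overrides ``config.seed`` (used for replicate draws). One root
    seed spawns independent child streams for the network signals and the
    idiosyncratic pixel noise.
    """
    root = config.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(root)
    rng_net, rng_pix = (np.random.default_rng(c) for c in ss.spawn(2))

    mask = elliptical_mask(config.grid_shape, config.mask_fraction)
    labels_vec = _assign_networks(mask, config.n_networks)
    label_img = np.zeros(mask.shape, dtype=int)
    label_img[mask.pixel_index[:, 0], mask.pixel_index[:, 1]] = labels_vec
    parcellation = Parcellation.from_labels(label_img, mask)

    T = config.n_frames
    phi = np.asarray(config.ar_coeff, dtype=float)
    if phi.ndim == 1 and phi.shape != (mask.n_pixels,):
        raise ValueError(
            f"per-pixel ar_coeff needs {mask.n_pixels} values (mask size), "
            f"got {phi.shape}")
    w = config.within_network_corr

    # latent network signals (scalar mean φ), Cholesky-mixed to the latent
    # correlation; per-pixel φ applies to the idiosyncratic components
    L = np.linalg.cholesky(config.latent_corr() + 1e-12 * np.eye(config.n_networks))
    nets = L @ generate_ar1_panel(config.n_networks, T, float(phi.mean()),
                                  rng_net)

    pix_noise = generate_ar1_panel(mask.n_pixels, T,
                                   phi if phi.ndim else float(phi), rng_pix)
    if w > 0:
        data = np.sqrt(w) * nets[labels_vec - 1] + np.sqrt(1 - w) * pix_noise
    else:
        data = pix_noise

    raw = RawSeries(data=data, fs=config.fs, mask=mask,
                    run_id=f"synthetic-{root}")
    if config.spatial_sigma > 0:
        size = 2 * int(np.ceil(2 * config.spatial_sigma)) + 1
        raw = spatial_smooth(raw, kernel_size=size, sigma=config.spatial_sigma)

    truth_tau = np.broadcast_to(ar1_tau(phi), (mask.n_pixels,)).copy()
    return SyntheticDataset(raw=raw, mask=mask, parcellation=parcellation,
                            truth_corr=config.truth_corr(),
                            truth_tau=truth_tau, config=config, seed=root)


def generate_null_pair(config: SyntheticConfig, seed_a: int,
                       seed_b: int) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two statistically independent runs with identical structure.

    Every cross-dataset true correlation is exactly zero — the synthetic
    analogue of correlating one mouse's pixels against another mouse's.
    """
    if seed_a == seed_b:
        raise ValueError("seed_a and seed_b must differ (independence)")
    return (generate_dataset(config, seed=seed_a),
            generate_dataset(config, seed=seed_b))
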