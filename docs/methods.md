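# Methods

This note documents the statistical model behind `oisconn`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter.

## Data model and preprocessing

The unit of analysis is a run: a pixel-by-time matrix of hemodynamic
values (e.g. ΔHbT) restricted to a binary brain mask, with a fixed
row-major pixel ordering shared by every downstream object. The
preprocessing chain is, in enforced order:

1. **Spatial smoothing** — each frame convolved with a truncated
   Gaussian (default 5×5, σ = 1 px), with the kernel renormalized over
   in-mask support so out-of-mask pixels contribute nothing and constant
   frames are preserved at mask edges.
2. **Bandpass + downsampling** — zero-phase 4th-order Butterworth
   (applied forward–backward with `sosfiltfilt`) over 0.01–0.1 Hz,
   then decimation by the integer factor fs/target_fs (default to 1 Hz).
   The 0.1 Hz low-pass edge already prevents aliasing at 1 Hz, so plain
   sample-picking decimation suffices.
3. **Global signal regression** — the mask-mean time course is regressed
   out of every pixel by OLS with intercept; residuals are orthogonal to
   the global signal. GSR runs after filtering (band-limited global
   signal) and before normalization.
4. **Normalization** — each pixel to zero mean, unit SD. Zero-variance
   pixels raise an error naming the offending rows rather than being
   silently dropped, so mask edits are explicit.

Runs may be concatenated time-wise (each run keeps its own
normalization; segment boundaries are recorded) and pixels may be
averaged within parcels of a label image, with re-normalization per
parcel.

## Variance of the correlation coefficient under autocorrelation

For normalized series, R(p,q) is the Pearson correlation and
F = arctanh R. The z-score is Z = F(1 − R²)/√V(R), which with the naive
variance V = (1 − R²)²/(T − 3) reduces exactly to Z = √(T−3)·F. Note the
displayed z-score equation in some renderings divides by V instead of
√V; the naive reduction fixes the intended form, which is what is
implemented.

### Autocorrelation time and the Bartlett correction

The per-pixel autocorrelation time is estimated as

    τ₁(p) = Σ_{i=0}^{M} ( wᵢ ρ̂ᵢ(p) )²,

with biased (divide-by-T) sample autocorrelations ρ̂ᵢ — the standard
choice that keeps the sequence positive semi-definite — Tukey taper
wᵢ = ½(1 + cos(πi/M)), and truncation at M = round(2√T) lags (a
configurable default; truncation at ~2√T is the usual compromise between
bias from cutting real tails and variance from summing noise lags). For
an AR(1) pixel with coefficient φ, τ₁ → Σφ^{2i} = 1/(1 − φ²), and the
estimator recovers this within a few percent at T = 300.

Two conventions for the Bartlett effective degrees of freedom
T̂ = T/⟨τ⟩ coexist, and the package deliberately uses both:

- the **single-sided** τ₁ above is the reported per-pixel map (it is the
  form written as a plain sum from lag 0 and the quantity with the clean
  AR(1) closed form);
- the **two-sided** completion τ₂ = 2τ₁ − 1 = Σ_{i=−M}^{M}(wᵢρ̂ᵢ)² is
  what the variance calibration uses by default, because the asymptotic
  null variance of the correlation of two independent stationary series
  is Var(R) ≈ (1/T)Σ_{k=−∞}^{∞} ρₓ(k)ρᵧ(k) — a two-sided sum. For
  equally-autocorrelated AR(1) pairs this is (1+φ²)/((1−φ²)T): using τ₁
  in T̂ would understate the variance by the factor 1/(1+φ²) (39% at
  φ = 0.8), which the Monte-Carlo calibration in the acceptance suite
  confirms, while τ₂ lands within ~5% of the empirical variance for
  φ ∈ {0, 0.5, 0.8}. Both conventions are exposed everywhere via
  `two_sided=` / `bartlett_two_sided=`; `bartlett_edof` itself is the
  plain arithmetic T̂ = T/⟨τ⟩ on whichever map it is given.

⟨·⟩ is the arithmetic mean over masked pixels by default (median
available); for cross-run null statistics the mean pools the pixels of
both runs. The Bartlett correction shrinks every z-score in a run by the
same factor √(T̂/(T−3)), an exact algebraic identity used as a test.

### xDF

The pairwise xDF variance uses the full tapered auto- and
cross-correlation sequences of the pair, truncated at the same M:

    V = (1/T²) [ (T−2)(1−R₀²)²
        + R₀² Σₖ (T−2−k)(Rₖ(p,p)² + Rₖ(q,q)² + Rₖ(p,q)²R₋ₖ(p,q)²)
        − 2R₀ Σₖ (T−2−k)(Rₖ(p,p)+Rₖ(q,q))(Rₖ(p,q)+R₋ₖ(p,q))
        + 2 Σₖ (T−2−k)(Rₖ(p,p)Rₖ(q,q) + Rₖ(p,q)R₋ₖ(p,q)) ]

The third entry of the R₀²-weighted sum is implemented as the product of
squares as written; a `cross_term="lag_product"` switch provides the
plain-product variant. Near the null (R₀ ≈ 0) the R₀²-weighted sum is
negligible, so the two variants are indistinguishable by the Monte-Carlo
calibration oracle, and the written form is kept as the default.

For white-noise pairs the formula's expected value is ≈ (T−2)/T², which
is *below* the naive value 1/(T−3) for every T > 3; unrestricted xDF
would then be anti-conservative at exactly the place the naive formula
is already right. V is therefore floored elementwise at the naive
variance and a per-pair flag records where the floor bound. Degenerate
pairs (|R₀| ≈ 1, e.g. the diagonal) get the floor evaluated at the
clipped correlation 1 − 10⁻⁷ so variances stay positive and finite;
such pairs never enter inference, which uses only the strict lower
triangle.

The full-matrix computation is vectorized with FFT cross-spectra and
chunked over rows to bound the P×P×(2M+1) workspace; each pair is a pure
function of its two series.

## FDR control

P-values are two-tailed normal, clamped above zero at the smallest
positive double. One Benjamini–Yekutieli pass covers the entire matrix:
the strict lower triangle for symmetric within-run matrices (N =
P(P−1)/2), all N = Pa·Pb entries for rectangular cross-run null
matrices, where every combination is a distinct test. BY rather than
Benjamini–Hochberg because pixel pairs are arbitrarily dependent
(spatial smoothness, shared networks, anticorrelations); the harmonic
penalty Σ1/j is computed directly. The strict inequality p₍ₖ₎ <
threshold is kept as the rule is stated; ties with the boundary value
share its fate through a stable (p, index) sort, and the difference from
the ≤ convention has probability zero for continuous p-values. Rejection
sets are provably nested in γ, so the sensitivity map (smallest grid γ
at which each pair is rejected, ∞ if never, over a 13-point log grid
from 10⁻⁵ to 10⁻²) is well defined.

## Synthetic data: what it emulates, what it does not

The generator produces the data regime the statistics are designed for:
5-min runs at 1 Hz (T = 300 by default), stationary AR(1) temporal
structure with φ = 0.75 by default (τ₁ ≈ 2.3 s, inside the 2–3.5 s range
typical of bandpassed hemodynamic data; per-pixel φ maps supported),
an elliptical brain mask echoing the dorsal field of view, planted
block networks realized exactly — each pixel is √w·(its network's latent
AR(1) signal, networks Cholesky-mixed to the latent correlation
b/w) + √(1−w)·(independent AR(1) noise), giving within-network pixel
correlation w = 0.7 and between-network correlation b = −0.3 at the
population level — optional Gaussian spatial smoothing inside the mask
(σ = 1 px default), and independent null pairs from disjoint seeds. The
implied latent correlation matrix is checked for positive
semi-definiteness at construction. One root seed spawns independent
child streams for network and pixel noise, and everything is
reproducible bit-for-bit from (config, seed).

Not emulated: hemoglobin spectroscopy and the Beer–Lambert conversion,
camera/shot noise, motion, heartbeat/respiration physiology, non-AR(1)
spectra beyond the bandpass (a filtered-noise generator is a possible
alternative left open), and realistic anatomical parcellations. Passing
tests therefore demonstrate correctness of the statistics under a known
stationary-autocorrelation model, not robustness to every artifact of
real recordings. Note that spatial smoothing raises within-network pixel
correlations above the nominal target (neighboring pixels share smoothed
noise), so exact-target checks use σ = 0.

## Problem sizes and determinism

Tests and the acceptance script use grids of 12×12–24×24 pixels
(~90–350 masked pixels), T = 300–10,000 frames, 5000-pair Monte-Carlo
panels for variance calibration, 500 replications for the FDR mixture,
and 50 replicate runs for end-to-end recovery — sizes at which every
oracle quantity is resolved well inside its test tolerance while the
whole suite runs in seconds. All randomness flows from explicit seeds
through `numpy.random.Generator`/`SeedSequence`; hypothesis-based
property tests are derandomized.

## Known limitations

- The Bartlett correction assumes spatially homogeneous autocorrelation;
  with strongly heterogeneous τ maps the single global T̂ misstates the
  variance of individual pairs (xDF is the per-pair alternative).
- xDF inherits ~O(P²M) cost; for very large masks compute it on parcels
  or use Bartlett, which is a single pass.
- The estimators are calibrated at the null; for strongly correlated
  pairs the Fisher-z normal approximation and the truncated sequences
  are approximate, which is why inference is on p-values with FDR
  control rather than on confidence intervals for R.
- Group-level (between-animal) inference, prewhitening, lagged or
  dynamic connectivity are out of scope.
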