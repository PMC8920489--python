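# oisconn

Which resting-state correlations are real? `oisconn` provides statistical
inference for pixel-pair Pearson correlations in widefield optical
intrinsic signal (OIS) functional-connectivity imaging of the mouse
cortex, where two kinds of autocorrelation break the textbook answer:

- **Temporal autocorrelation.** Hemodynamic time series H(p, t) —
  bandpassed to 0.01–0.1 Hz and sampled at 1 Hz — are strongly
  autocorrelated, so the T frames of a run carry far fewer than T
  independent observations. The naive variance of a Pearson correlation,
  V(R) = (1 − R²)²/(T − 3), is then much too small and z-scores are
  spuriously inflated.
- **Spatial multiplicity.** A correlation matrix over ~10⁴ masked pixels
  contains ~5·10⁷ distinct pairs; uncorrected thresholding (|z| > 2)
  declares a large fraction of pure-noise pairs significant.

## The statistics

Correlations are Fisher-transformed, F = arctanh R, and converted to
z-scores

    Z = F · (1 − R²) / sqrt(V(R))

with three interchangeable variance estimators:

- **naive** — V = (1 − R²)²/(T − 3), so Z = sqrt(T − 3)·F; valid only
  without autocorrelation.
- **Bartlett** — V = (1 − R²)²/T̂ with effective degrees of freedom
  T̂ = T/⟨τ⟩, where the autocorrelation time τ(p) of each pixel is the
  sum of squared, Tukey-tapered sample autocorrelations truncated at
  M = round(2√T) lags, and ⟨·⟩ averages over the brain mask. The reported
  per-pixel map uses the single-sided sum Σ_{i=0..M}(wᵢρ̂ᵢ)² (equal to
  1/(1 − φ²) for an AR(1) pixel); the variance calibration uses its
  two-sided completion 2τ − 1 = Σ_{i=−M..M}(wᵢρ̂ᵢ)², the classical
  Bartlett sum that matches the true null variance of R (see
  `docs/methods.md`).
- **xDF** — a per-pair estimator built from the full tapered auto- and
  cross-correlation sequences of the pair, assuming only stationarity,
  and floored elementwise at the naive variance.

Two-tailed normal p-values from the chosen estimator are thresholded
*once per correlation matrix* (strict lower triangle for within-run data;
every entry for cross-run null data) with the **Benjamini–Yekutieli**
step-up procedure, which controls the false discovery rate at level γ
under arbitrary dependence: rank the N p-values ascending and reject the
k* smallest, where k* is the largest k with p₍ₖ₎ < (k/N)·γ/Σⱼ₌₁ᴺ(1/j).

A synthetic-data generator (`oisconn.synthetic`) emulates the data
regime — 5-minute 1 Hz runs, AR(1) temporal structure with τ of a few
seconds, Gaussian spatial smoothness, planted correlated/anticorrelated
pixel networks, and matched independent null pairs — so every stage has
exact ground truth.

## Worked example

`examples/null_calibration.py` correlates every pixel of one synthetic
run against every pixel of an independent run (all true correlations
zero, AR(1) pixels with φ = 0.75):

```
null pair: 156 x 156 = 24336 cross-run pixel pairs, AR(1) phi=0.75
naive     KS=0.1490  |z|>2:  29.0%  significant at FDR 1e-3: 0.75%
bartlett  KS=0.0061  |z|>2:   4.8%  significant at FDR 1e-3: 0.00%
xdf       KS=0.0177  |z|>2:   6.2%  significant at FDR 1e-3: 0.00%
```

The naive z-scores are far from N(0, 1) (KS 0.15) and 29% of null pairs
pass |z| > 2; after Bartlett or xDF correction the z distribution is
near-normal and FDR control leaves essentially no false positives.
`examples/simulate_and_recover.py` runs the full pipeline on a
planted-network run and recovers 100% of within-network pairs at
FDR 10⁻³; `examples/tau_maps_and_parcels.py` and `examples/fdr_sweep.py`
demonstrate τ maps, parcel averaging, and the FDR sensitivity sweep.

The same stages are available as a thin CLI:

```
oisconn simulate --out sim/ --seed 1
oisconn pipeline --in sim/series.h5 --mask sim/mask.tif --out results/
```

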