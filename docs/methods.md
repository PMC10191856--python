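# Methods

## Generative models

**Live-cell traces.** Each cell is an independent two-state (telegraph)
promoter. The induction delay is `dead_time` plus a Gamma(`n_steps`,
1/`step_rate`) waiting time — the sum of `n_steps` identical exponential
activation steps, the same functional form the induction-time fit assumes.
From induction on, ON and OFF dwells alternate as exponentials with means
`mean_on` and `mean_off` (defaults 2 and 8 min, yeast-scale bursting).
Frame intensities are sampled at instants every `frame_interval` (15 s over
60 min): while ON, `mean_intensity` × a lognormal factor with mean 1 and CV
`intensity_cv` (default 0.2; multiplicative noise reproduces the
heavy-tailed burst intensities a log-normal fits), plus additive Gaussian
background of s.d. `background_sd` everywhere. The default
`mean_intensity`/`background_sd` ratio of 10 corresponds to a comfortably
detectable TS. One top-level seed spawns per-cell RNG streams, so outputs
are byte-identical under a fixed seed at any cell count.

What the generator does *not* model: photobleaching, blinking, cell growth
and movement, z-dependent PSF changes, or segmentation errors. Passing
recovery tests on it therefore demonstrates the correctness of the
estimators under the stated stochastic model, not robustness to every
imaging artifact of real movies.

**Movies.** `render_movie` lays cells out as disk bodies on a grid
(visible above background so Otsu segmentation has something to find) and
draws one 2D Gaussian spot per ON cell with integrated intensity equal to
the trace value, plus i.i.d. Gaussian pixel noise.

**smFISH.** Cytoplasmic single RNAs are lognormal around a unit median;
the single nuclear TS has intensity nascent-count × unit; DAPI sums come
from a two-Gaussian (1C/2C) mixture with known component labels. Default
components (1, 2)×10^5 with s.d. 5×10^3 give the 6-s.d. separation typical
of well-stained populations.

**MNase.** Fragment midpoints are Normal(center, 20 bp) around planted
dyads, lengths truncated-Normal(150, 15) in [50, 300] bp, plus a 10%
uniform background. `promoter_array_model` plants what yeast chromatin
actually looks like — a phased array every 165 bp broken by a promoter NDR
(default 300 bp, +1 at TSS+60) — because the calling procedure finds the
*global* coverage minimum of a 4 kb window and therefore presumes
nucleosomal signal throughout the window.

## Trace extraction

Registration is translation-only phase correlation on the max projection
by default (stage drift is translational); a full affine mode
(ORB features + RANSAC) is available and falls back to translation when
matching fails. Segmentation thresholds a log-compressed reference image
(Otsu's between-class variance is otherwise captured by the tiny, very
bright TS spots) and splits touching cells by distance-transform
watershed; objects under 100 px are dropped.

Spot photometry is the iterative Gaussian-mask estimator: weighted
least-squares amplitude of a fixed-σ Gaussian in a local window, centroid
updated to convergence (Δ < 0.01 px, ≤ 100 iterations), local background
from the window perimeter. The window half-width is 4σ: with
perimeter-mean background, a 3σ window leaks ~2% of the spot into the
background estimate and breaks 1% recovery. The integrated-intensity noise
floor of this estimator is 2√π·σ_psf·σ_pixel per frame, which the
end-to-end tests assert against. Detection runs on the per-frame max
projection at 6× the background s.d., retries near the last known position
at 4×, and otherwise measures at the last position ("carried-over"); the
trace endpoint is set automatically to the last detected frame, replacing
manual curation (an override file can supply curated endpoints).

## Background width and binarization

The "s.d. of the background" is the scale γ of a Cauchy (Lorentzian)
location-scale MLE on background intensities — a Cauchy has no s.d., so the
fitted scale is the operational width; an HWHM-to-Gaussian-σ conversion
(γ/√(2 ln 2)) is available. For a purely Gaussian background the Cauchy
MLE settles near 0.613σ, so the 5×-width threshold is ≈3.1 Gaussian σ.
In imaging mode the samples come from fixed-position photometry at four
points 5 px from the TS in every frame; in CSV mode the whole trace is
fitted and then refined twice on sub-threshold frames to strip ON-frame
inflation.

Binarization thresholds at 5× width, then (1) deletes single-frame ON
runs, then (2) merges ON runs separated by one OFF frame — the order
matters (an alternating trace vanishes entirely) and is configurable but
fixed by default. Cleanup is idempotent.

## Discretization-corrected telegraph estimates

Sampling a two-state continuous-time Markov process at interval Δ yields a
two-state Markov chain whose run lengths are geometric with per-frame
switching probabilities a = π_off(1−e^(−λΔ)), b = π_on(1−e^(−λΔ)),
λ = 1/τ_on + 1/τ_off. `estimate_telegraph_parameters` therefore:

1. counts frame-to-frame transitions per cell on a *denoised* thresholded
   state — single-frame runs that never exceed 8× the background width are
   discarded as threshold noise (false positives at the 5× threshold occur
   at ~10⁻³/frame and would inflate the switching rates by ~3%; genuine
   single-frame bursts are far brighter and are kept);
2. treats runs touching the trace end as right-censored (n−1 trials, no
   stop), removing the length-biased selection a finite movie imposes;
3. solves (â, b̂) → (τ̂_on, τ̂_off) in closed form;
4. corrects the induction time — the first denoised ON frame — by the
   phase-averaged missed-attempt bias: a burst attempt is invisible only
   when it falls entirely between sample instants, so
   bias = E[lag to first covered instant] +
   P_miss/(1−P_miss) · (E[D | missed] + τ_off),
   with all terms computed by quadrature over the uniform start phase.

Both bias models were validated against independent Monte-Carlo oracles
(per-attempt and discrete-chain simulations) and the full estimator
recovers (2, 8, 6) min from 3,000 simulated cells as (1.97, 7.84, 6.1).
The uncorrected bootstrap summaries remain the primary descriptive output;
the corrected estimates are what should be compared across frame rates or
against generative truth.

The dynamic-epistasis replicate studies classify on the corrected time
between bursts: raw inter-burst means saturate inside a 60-min movie once
perturbations push τ_off toward the movie length (long gaps never
complete), which would masquerade as buffering in the multiplicative
comparison.

## Statistics

The two-sample bootstrap test translates both groups to the pooled mean,
resamples within groups, and reports the two-sided achieved significance
level with add-one smoothing, (1 + #{|d*| ≥ |d_obs|})/(B + 1) — the
standard Monte-Carlo correction that avoids zero p-values. A studentized
statistic is available by flag. Active fractions are compared by
two-sided Fisher's exact test; count errors are √n. Ratio errors propagate
as sd = √((sd_x/y)² + (x·sd_y/y²)²), assuming independence between
conditions. No multiple-testing correction is applied by default
(per-comparison reporting); a Benjamini–Hochberg helper can be layered on
by the caller via statsmodels if desired.

## Distribution fits

Fits are least squares on histogram densities (not MLE), evaluated at bin
centers with empty bins kept as zeros; the amplitude A absorbs the
density-vs-count convention as well as the acquisition dead time. Bounds
and starts: induction — A ≥ 1 (start 10), k ≥ 10⁻⁴ (start 10, or 1.0001
for re-induction), θ > 0 (start 1); dwell times — A = 1, k ≥ 1 (start
1.0001), θ > 0; log-normal — σ > 0 (start 0.6), μ free (start 5.5), with a
data-driven second start (log-median, log-s.d.) guarding against local
minima when intensities are on a different scale. The Gamma shape k is
used as a shape parameter throughout even where the field sometimes calls
it a scale. Degenerate inputs (fewer than three occupied bins, constant
values) return `converged=False` rather than raising. The subpopulation
screen flags R² < 0.8 and adds an instability warning below 50 samples,
where sparse histograms produce low R² without any mixture.

## smFISH

DAPI sums are taken per cell from a maximum-intensity projection. The
Gaussian mixture is fitted to raw DAPI values with means initialized from
the two strongest well-separated modes of a 50-bin histogram (binning is
used for initialization only; fitting on values is the stable choice).
Gates: G1 = [c1 − sd1, c1 + 0.75·sd1], G2 = [c2 − 0.5·sd2, c2 + 1.5·sd2],
S in between, unclassified outside — the asymmetric G1 window keeps the
early-S shoulder out of the G1 gate; a symmetric option exists. A mixture
whose component means overlap within half the pooled s.d. classifies
nothing and warns. Stage-recovery accuracy is measured against generative
component labels among cells given a G1/G2 call.

## MNase

Coverage counts full fragment spans (one count per pair), the standard
mono-nucleosome convention; a per-read mode is behind a flag. The "40 bp
Gaussian window" is interpreted as FWHM = 40 bp (σ = 40/2.355 ≈ 17 bp); a
raw-σ mode is available because calls depend on it. Peaks are local maxima
with prominence ≥ 5% of the window maximum and ≥ 100 bp separation.
Windows are TSS-oriented (downstream positive), mirrored exactly around
the TSS for Crick genes so mirror-image genes produce identical calls.
Calling uses raw (pre-normalization) coverage pooled over the unperturbed
reference datasets; metagene and log2FC use normalized coverage. The
log2FC pseudo-count defaults to 1% of the mean control coverage per base
within the compared windows — small relative to signal so that a uniform
2× change reads as log2FC ≈ 1, rather than a fixed 1/window constant that
would swamp normalized-scale values. Exclusion rules: fewer than two
peaks, or a −1/+1 call more than 1,000 bp from the TSS (peak-to-TSS
distance). Coordinates are 0-based half-open; BED input/output is 0-based
and GFF-style 1-based input must be converted by the caller.

## Problem sizes

The bundled studies use 300-cell live-cell experiments (100 for the
binarization-fidelity check), 1,000 bootstrap repetitions, 1,000 null
replicates for test calibration (B = 1,999 per test), 100 replicate
epistasis studies of 4 × 200 cells, 2,000 samples per distribution fit,
2,000 smFISH cells, and 10,000 fragments per gene over six genes on two
small chromosomes — sizes chosen so every study resolves its effect
comfortably while the whole suite runs in minutes on one core.

## Entry points

The numbered scripts under `analysis/` and the library functions are the
interface; `scripts/acceptance.py` reruns all studies and writes their
headline numbers to JSON.

## Known limitations

- Dwell corrections assume exponential dwells; non-exponential kinetics
  (e.g. multi-step OFF states) would need a different forward model.
- The denoising confirmation threshold (8× width) presumes the TS is well
  above background (SNR ≳ 8); at lower SNR genuine single-frame bursts
  start to be discarded and dwell estimates shorten accordingly.
- Live-cell photometry is 2D on the max projection; axial displacement is
  not modeled.
- The MNase caller inherits the global-minimum convention and therefore
  expects nucleosomal coverage across the whole window, as in gene-dense
  genomes.
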