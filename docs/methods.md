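# Methods

This note documents the models, the synthetic-data regime, the numerical
choices and the known limitations of `aslica`.

## Signal model and quantification

The kinetic forward model is the single-compartment general kinetic model
for pseudo-continuous labeling: a boxcar of labeled blood of duration τ
arrives after the arterial transit time Δt and relaxes with the apparent
tissue constant 1/T1app = 1/T1t + f/λ. Constants default to 3 T consensus
values — T1b = 1.65 s, T1t = 1.3 s, α = 0.85, λ = 0.9 ml/g, τ = 1.8 s —
and are all configurable. CBF is expressed in ml/100g/min throughout the
API (divided by 6000 inside the model); the arterial magnetization is the
(optionally smoothed) M0 calibration image divided by λ.

Fitting is voxelwise nonlinear least squares over all retained difference
volumes, with repeats entering as replicate observations rather than being
pre-averaged, so that any change in temporal variance produced by
denoising propagates into the reported CBF/ATT standard errors. Two
implementations exist and are tested against each other:

* `fit_voxel` — the reference path: `scipy.optimize.least_squares` with a
  multi-start over ATT ∈ {0.3, 0.7, 1.1, 1.5, 1.9} s, bounds
  f ∈ [0, 300] ml/100g/min and Δt ∈ [0.1, 3.0] s.
* `KineticFitter` — the batched path used on images: ATT is profiled on a
  dense grid (0.02 s step) with f solved per grid point by iterated linear
  least squares (the T1app(f) link absorbed by two fixed-point updates),
  then polished with damped Gauss-Newton steps, all vectorized across
  voxels. On the noiseless phantom both paths agree to well below the
  reported uncertainties; the batched path fits a masked 32×32×8 dataset
  in well under a second.

Uncertainty is the Jacobian-based covariance scaled by residual variance;
`z = f/sd(f)`, and gray-matter voxels with z < 2 (strict) or failed
convergence count as poorly fitted. Spatially regularized inference is out
of scope; an optional Gaussian smoothing of M0 (default σ = 1 voxel)
is the only spatial coupling.

Scale equivariance (doubling M0a halves fitted f) holds only up to the
T1app(f) nonlinearity — about 0.6% at f = 60 — and is asserted at 1% in
the tests.

## Decomposition

The subtracted series is arranged as a T × V matrix over in-brain voxels
and double-centered (per-voxel temporal mean, then per-volume spatial
mean); the temporal mean — the perfusion-weighted image itself — is never
touched by any denoiser and is restored after regression.

Model order comes from the Laplace approximation to the probabilistic-PCA
evidence (Minka's criterion) on the covariance eigenspectrum. Temporal
demeaning leaves one exact null eigenvalue, so the evidence is evaluated
on the top T−1 eigenvalues, and the admissible order is additionally
bounded by the numerical rank (near-noiseless data would otherwise defeat
the PPCA noise floor). K is clamped to [2, T−2].

The ICA itself is symmetric fixed-point iteration with the logcosh
contrast on PCA-whitened spatial sources, restarted 5 times from seeded
random rotations, keeping the run with the highest total negentropy.
Conventions: spatial maps z-scored over voxels, mixing columns
unit-variance over time, components ordered by descending explained
variance, map sign fixed by non-negative skewness; per-component
amplitudes are stored so the retained-order PCA reconstruction is exactly
recoverable. Voxelwise variance normalization before decomposition is off
by default — the amplitude structure of the subtracted series is
informative — and available as an option.

On the default synthetic corpus the estimated order equals the generative
one (three structured components + one perfusion component). Clinical
multi-PLD data yield substantially higher orders; the synthetic corpus
validates the estimator's selection behavior, not the clinical range.

## Component classification

Eight features are computed per component: GM overlap, edge-ribbon and
periventricular fractions of the top-decile |z| voxels; the fraction of
time-course periodogram power in the PLD-cycle fundamental (n_repeats
cycles per scan, 6 by default) and its harmonics; R² of the time course on
the cycled PLD-block indicator basis; maximum |correlation| with the six
pair-averaged motion parameters and their first differences; the maximum
standardized time-course excursion; and the normalized spectral entropy.

The rating rule calls a component signal iff at least two of three
criteria hold: (A) spatially GM-like (GM overlap ≥ 0.4 and edge fraction
≤ 0.3); (B) time course congruous with the PLD schedule (block-basis R² ≥
0.5); (C) spectral power concentrated at the PLD-cycle frequency (power
ratio ≥ 3× the exchangeability baseline, i.e. the matched-bin share of
positive-frequency bins, 2/15 for 30 volumes and 6 repeats). The numeric
cutoffs operationalize qualitative rating criteria and were calibrated on
the synthetic corpus, where PLD-locked perfusion components score R² and
power ratio above ~0.6 while artifact components stay below ~0.35; they
are all configurable.

The trained route is a standardized logistic model over the same features.
Training is leave-one-subject-out: the decision threshold is chosen on
pooled out-of-fold probabilities as the one granting the highest true
negative ratio while keeping the true positive ratio above 90% (exact
optimum over threshold midpoints; `prob ≥ threshold` is signal, boundary
inclusive). Models serialize to JSON.

## Denoising

* **Non-aggressive regression** fits *all* K mixing time courses jointly
  (`β = pinv(M)·Y` on demeaned data) and subtracts only the noise
  partition `M[:, noise]·β[noise]`, retaining variance shared between
  signal and noise components. An aggressive variant projects out the
  noise span alone.
* **aCompCor** linearly detrends the WM/CSF-ROI time series, extracts the
  top principal-component time courses (default 5), orthogonalizes them
  against intercept + linear trend, and projects them out of every voxel;
  each voxel's mean and trend are retained.
* **ENABLE-style scrubbing** greedily removes single difference volumes.
  Candidates are scored by the composite of the four quality criteria —
  tCNR, proportion of GM voxels significantly above zero (one-sided t,
  α = 0.05, uncorrected), spatial CoV (negated), tSNR — z-scored across
  the candidate pool. A removal is applied only when it is a genuine
  outlier: its composite gain must be positive and exceed the mean gain
  of the other candidates by 3 standard deviations. Without this gate the
  maximum over ~T exchangeable candidates beats the current subset almost
  surely and the chain scrubs ordinary volumes; with it, exchangeable
  data lose at most one volume in ≥ 8/10 seeds while a 10σ corrupted
  volume is removed first. A per-PLD retention floor guarantees at least
  one volume per PLD. This greedy-with-gate procedure is this package's
  operational definition of the comparator.

The tSNR ambiguity (spatial-statistic vs per-voxel temporal reading) is
resolved to the conventional per-voxel temporal mean/std averaged over GM;
the literal spatial reading is available behind a flag. Standard
deviations are sample (n−1) throughout.

## Synthetic data

The phantom is a concentric ellipsoidal head: CSF ventricle (radial
fraction < 0.30), WM core (0.30–0.62), GM shell (0.62–1.0), with trapezoid
partial-volume transitions of width 0.15 so each compartment keeps an
exact plateau at fraction 1 (pure-tissue voxels exist by construction).
Tissue truth defaults to GM CBF 60 / WM CBF 20 ml/100g/min and GM ATT
1.0 / WM ATT 1.4 s — textbook values placed inside the PLD range so every
segment of the kinetic curve is exercised. M0 is tissue-weighted with 2%
smooth texture; background suppression is a single scalar attenuation of
static tissue (0.1 of M0), leaving ΔM unscaled.

Control volumes carry the suppressed static signal; label volumes
subtract the kinetic ΔM at each voxel's PVE-weighted CBF/ATT. Structured
noise is planted as exact rank-1 space-time components written ±half onto
control/label, so pairwise subtraction reproduces the planted difference
contribution exactly — the generator is its own ground truth in the
difference domain. The three structured kinds and the reasoning behind
their geometry:

* **motion-edge** — smooth field on the brain-boundary ribbon dilated by
  one voxel (subtraction errors at the edge bleed into the outer GM rim,
  which is what makes corrupted volumes visible to GM-based quality
  criteria); time course = 3 spikes at seeded random volumes, echoed as
  spikes in the motion-parameter traces.
* **drift** — one cosine cycle per scan on a saturating left-right (tanh)
  field. The field is strong in the WM/CSF core (so a WM/CSF noise ROI
  carries it), odd in x (so it is spatially near-orthogonal to the
  radially symmetric perfusion pattern and cleanly separable by spatial
  ICA), and the cosine phase has no linear-trend component (so
  trend-preserving cleanup sees the full oscillation).
* **CSF pulsation** — white time course on a periventricular field.

Maps are normalized to unit RMS over in-brain voxels and courses to unit
peak, so an amplitude is the per-voxel RMS excursion in signal units at
the course peak. Defaults: structured amplitudes 10, thermal σ = 2 — a
5:1 ratio, the regime in which all planted maps are recoverable by ICA at
spatial correlation ≥ 0.95. GM ΔM peaks near 9 signal units with the
default phantom, so structured artifacts dominate the perfusion signal,
as in a motion-prone clinical population; in this regime the method
ordering of the denoisers (ICA ≫ aCompCor > ENABLE > raw) and an ENABLE
removal count of ~0–3 volumes emerge from the generator rather than being
asserted.

What the generator does **not** emulate: real head-motion resampling
(motion exists only as the planted edge component plus parameter spikes),
arterial/macrovascular signal, dispersion, EPI distortion, physiologic
noise spectra, lesions, and the component richness of clinical data
(tens of ICs). Passing tests therefore demonstrate correctness of the
algorithms in a controlled regime, not clinical performance.

## Evaluation suite

%ΔSTD = 100·(STD_orig − STD_corr)/STD_orig per voxel (temporal, n−1);
probability maps are threshold-(default 25%)-binarized ΔSTD maps averaged
across datasets. The CBF/ATT summary per GM mask: mean of the value map,
mean of sd², and SNR = mean of value/sd, over converged voxels.
Repeatability splits the series into epochs of one repetition per PLD,
fits each epoch independently (same multi-start, no warm start) and
reports the across-epoch CoV of GM-mean CBF. The repetition experiment
retains the first k repetitions (last acquired removed first), k from
n_repeats down to 2, optionally re-denoising each truncation, and records
CBF-SNR.

Under the full structured-noise profile the raw repetition curve need not
be monotone — discarding late repetitions can discard planted spike
artifacts — so the averaging property (SNR non-increasing as repetitions
drop) is established under thermal-only noise, while the headline
"denoised half of the data beats the full raw data" property is
established at the default full profile.

## Reproducibility

All randomness is seeded: one master seed fans out to phantom texture,
noise courses, ICA restarts and classifier fitting. Identical config +
inputs give byte-identical metric tables; every pipeline run writes a
provenance record (config hash, seeds, versions, output list).

## Known limitations

* The rating rule is threshold-based; when ICA separation is partial
  (e.g. unlucky spike placements at small K), a motion component that has
  absorbed perfusion variance can cross two criteria and be kept. Human
  raters and trained classifiers in the target workflow are imperfect in
  the same way; the trained route with LOSO threshold selection is the
  more robust option on a corpus.
* aCompCor's noise ROI unavoidably contains perfusing WM, so its nuisance
  subspace absorbs some PLD-locked signal; this is a property of the
  method, visible here because ground truth is known.
* The dimensionality estimator is validated on low-order synthetic data;
  its behavior at clinical orders (15–25 components) is untested here.
* Voxelwise fitting without spatial priors is noisier than regularized
  variational inference at matched data quality; absolute clinical values
  are not comparable.

## Problem sizes

Default grid 32×32×8 (≈2,500 brain voxels, ≈1,700 GM voxels at the 70%
PVE threshold), 5 PLDs × 6 repeats (30 difference volumes). The
comparison corpus is 10 subjects; training corpora for the LOSO
classifier use 3–4 subjects. These sizes were chosen so the entire
validation suite, including the multi-method comparison and repetition
experiment, runs in minutes on a single CPU while every stage of the
method is still exercised end to end.
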