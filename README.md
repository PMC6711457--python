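# aslica

ICA-based denoising and kinetic quantification for multi-PLD arterial spin
labeling (ASL) perfusion MRI.

ASL measures cerebral perfusion by magnetically labeling arterial blood and
subtracting labeled from control images. The difference signal is tiny
(~1% of the static tissue signal), so the subtracted series (ASL-sub) is
dominated by thermal noise and structured artifacts — motion-related
subtraction errors at the brain edge, slow scanner drift, CSF pulsation.
`aslica` separates signal from structured noise by single-subject **spatial
ICA**: each independent component is classified as perfusion signal or
artifact — either by an explicit three-criteria rating rule or by a trained
classifier — and the artifact components are removed by **non-aggressive
regression**, which subtracts only the variance uniquely attributable to
them. Two standard comparators are included: **aCompCor** (nuisance
regression on principal components of a WM/CSF noise region) and an
**ENABLE**-style volume scrubber (greedy removal of poor-quality difference
volumes under combined quality criteria).

Quantification uses the single-compartment pCASL general kinetic model.
With label duration τ, post-labeling delay (PLD) w, arterial blood
magnetization M0a, labeling efficiency α, and apparent tissue relaxation
1/T1app = 1/T1t + f/λ, the difference signal at t = τ + w is

```
ΔM(t) = 0                                                      t < Δt
ΔM(t) = 2 M0a α f T1app e^(−Δt/T1b) (1 − e^(−(t−Δt)/T1app))    Δt ≤ t < Δt+τ
ΔM(t) = 2 M0a α f T1app e^(−Δt/T1b) e^(−(t−Δt−τ)/T1app) (1 − e^(−τ/T1app))
```

where f is CBF (ml/100g/min, converted internally to ml/g/s) and Δt the
arterial transit time (ATT). Sampling several PLDs lets a voxelwise
nonlinear least-squares fit estimate CBF and ATT jointly, with
Jacobian-based standard errors; `z = CBF/sd(CBF)` marks fit confidence and
`CBF-SNR` is the gray-matter mean of the voxelwise CBF/sd ratio.

Because no clinical data ship with the package, a synthetic pCASL generator
(`aslica.synthgen`) produces the full study surface: a concentric
tissue phantom (GM shell / WM core / CSF ventricle, smooth partial-volume
boundaries), the looped multi-PLD acquisition of the method's target
protocol (5 PLDs of 0.4–2.0 s, τ = 1.8 s, 6 repeats, 60 volumes), and
planted rank-1 structured noise with exact ground truth.

## Worked example

```bash
aslica simulate --grid 32 32 8 --seed 5 --noise-profile full --out ds
aslica run --dataset ds --seed 5 --out out
aslica fit --dataset ds --out out/raw_fit
```

The `run` command subtracts, decomposes, classifies, regresses the noise
components, refits the kinetic model and prints:

```
ica-nonaggr: GM CBF 59.1, CBF-SNR 11.83
```

while the raw fit (no denoising) prints:

```
GM CBF 59.1 ml/100g/min, ATT 0.61 s, CBF-SNR 4.57
```

The planted gray-matter CBF is 60 ml/100g/min: denoising leaves the mean
CBF essentially unbiased while raising the CBF-SNR from 4.6 to 11.8,
because removing the planted motion/drift/pulsation components shrinks the
voxelwise fit uncertainty. Per-stage outputs (MELODIC-style `melodic_IC` /
`melodic_mix`, FIX-dialect label file, %ΔSTD map, CBF/ATT/uncertainty
maps, metric CSV, provenance record) land in `out/`.

The multi-method comparison across a corpus of datasets:

```bash
aslica compare --corpus ds1 --corpus ds2 --corpus ds3 --seed 1 --out cmp
```

produces one metric row per (dataset, method) for raw, rule-classified ICA,
LOSO-trained ICA, aCompCor and ENABLE.

## File formats

NIfTI-1 images (float32); 6-column whitespace motion parameters, rotations
(radians) before translations (mm); FIX "hand-labels" dialect for component
labels (final line = bracketed 1-based noise list); YAML acquisition
descriptors (`plds_s`, `tau_s`, `n_repeats`, `order`, `tr_s`); CSV metric
reports.
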