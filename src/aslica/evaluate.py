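"""Metrics for judging denoising quality.

Covers the volume-quality criteria (tCNR, proportion of GM voxels
significantly above zero, spatial CoV, tSNR), %dSTD maps and their
threshold-probability summaries, CBF/ATT-SNR summaries, poor-fit counts,
epoch-split repeatability, and the repetition-reduction experiment.

Conventions: standard deviations are sample (n-1) throughout; the GM
summary statistic is the mean (median available via ``agg``);
"significantly greater than zero" is a per-voxel one-sided t-test at
alpha = 0.05, uncorrected (a scalar quality summary, not an inference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from aslica.asl_io import ImageSeries
from aslica.kinetics import KineticConstants, PerfusionFit, fit_dataset
from aslica.preprocess import AslSub

__all__ = [
    "QualityCriteria",
    "quality_criteria",
    "delta_std_map",
    "delta_std_probability",
    "snr_summary",
    "split_epochs",
    "repeatability_cov",
    "repetition_curve",
    "poor_fit_count",
]


@dataclass(frozen=True)
class QualityCriteria:
    """The four volume-quality summaries of a difference series."""

    tcnr: float
    prop_gt_zero: float
    cov: float
    tsnr: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tcnr, self.prop_gt_zero, self.cov, self.tsnr])


def quality_criteria(
    sub: AslSub,
    gm: np.ndarray | None = None,
    nonbrain: np.ndarray | None = None,
    alpha: float = 0.05,
    tsnr_literal_spatial: bool = False,
) -> QualityCriteria:
    """Compute tCNR, prop>0, CoV and tSNR of a difference series.

    * tCNR: GM mean of the per-voxel temporal mean, divided by the
      standard deviation of all non-brain samples.
    * prop_gt_zero: fraction of GM voxels whose time series is
      significantly greater than zero (one-sided t, ``alpha``).
    * CoV: spatial std / spatial mean of the temporal-mean map in GM.
    * tSNR: GM mean of per-voxel temporal mean / temporal std (the
      conventional reading; ``tsnr_literal_spatial`` switches to the
      literal spatial-statistic reading: spatial mean / spatial std of
      the temporal-mean map).
    """
    gm = gm if gm is not None else sub.gm_mask
    nonbrain = nonbrain if nonbrain is not None else sub.nonbrain_mask
    if gm is None or not np.any(gm):
        raise ValueError("empty GM mask")
    if nonbrain is None or not np.any(nonbrain):
        raise ValueError("empty non-brain mask")
    gm = gm.astype(bool)
    nonbrain = nonbrain.astype(bool)

    T = sub.n_volumes
    gm_ts = sub.data[gm, :]  # Vgm x T
    tmean = gm_ts.mean(axis=1)
    tstd = gm_ts.std(axis=1, ddof=1)

    nb_samples = sub.data[nonbrain, :].ravel()
    nb_std = float(np.std(nb_samples, ddof=1))
    tcnr = float(tmean.mean() / nb_std) if nb_std > 0 else np.inf

    tcrit = stats.t.ppf(1 - alpha, df=T - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = tmean / (tstd / np.sqrt(T))
    prop = float(np.mean(tstat > tcrit))

    sp_mean = float(tmean.mean())
    sp_std = float(np.std(tmean, ddof=1))
    cov = sp_std / sp_mean if abs(sp_mean) > 1e-12 else np.inf

    if tsnr_literal_spatial:
        tsnr = sp_mean / sp_std if sp_std > 0 else np.inf
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(tstd > 0, tmean / tstd, 0.0)
        tsnr = float(ratio.mean())

    return QualityCriteria(tcnr=tcnr, prop_gt_zero=prop, cov=cov, tsnr=tsnr)


def delta_std_map(orig: AslSub, corrected: AslSub) -> np.ndarray:
    """Percent reduction of the per-voxel temporal standard deviation.

    ``100 * (STD(orig) - STD(corrected)) / STD(orig)``; the corrected
    series may have fewer volumes (volume scrubbing).  Voxels with zero
    original STD are set to 0.
    """
    if orig.grid != corrected.grid:
        raise ValueError("series grids differ")
    s0 = orig.data.std(axis=3, ddof=1)
    s1 = corrected.data.std(axis=3, ddof=1)
    out = np.zeros(orig.grid, dtype=float)
    ok = s0 > 0
    out[ok] = 100.0 * (s0[ok] - s1[ok]) / s0[ok]
    return out


def delta_std_probability(
    maps: list[np.ndarray], threshold: float = 25.0
) -> np.ndarray:
    """Per-voxel fraction of %dSTD maps at or above ``threshold``."""
    if not maps:
        raise ValueError("empty map list")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps must share a grid")
    stack = np.stack(maps, axis=0)
    return (stack >= threshold).mean(axis=0)


def snr_summary(
    fit: PerfusionFit,
    gm: np.ndarray,
    agg: Callable[[np.ndarray], float] = np.mean,
) -> dict:
    """GM summaries: mean value, mean sd^2 (variance) and SNR per map.

    SNR is the GM aggregate of the per-voxel value / sd ratio.
    Non-converged voxels are excluded.
    """
    gm = gm.astype(bool)
    ok = gm & fit.converged & np.isfinite(fit.sd_cbf) & (fit.sd_cbf > 0)
    if not np.any(ok):
        raise ValueError("no converged GM voxels")
    cbf, sd_c = fit.cbf[ok], fit.sd_cbf[ok]
    att, sd_a = fit.att[ok], fit.sd_att[ok]
    return {
        "cbf_mean": float(agg(cbf)),
        "cbf_variance": float(agg(sd_c**2)),
        "cbf_snr": float(agg(cbf / sd_c)),
        "att_mean": float(agg(att)),
        "att_variance": float(agg(sd_a**2)),
        "att_snr": float(agg(att / sd_a)),
        "n_voxels": int(ok.sum()),
    }


def split_epochs(sub: AslSub, strict: bool = True) -> list[AslSub]:
    """Split into epochs of one repetition per PLD.

    Epoch ``r`` holds the retained volumes whose original schedule index
    falls in repetition ``r``, in PLD order.  With ``strict`` every epoch
    must contain exactly one volume per PLD (violated after volume
    scrubbing, where ``strict=False`` keeps partial epochs that still
    span >= 2 distinct PLDs).
    """
    P = sub.acq.n_plds
    n_rep = sub.acq.n_repeats
    epochs = []
    for r in range(n_rep):
        in_epoch = (sub.volume_ids // P) == r
        idx = np.where(in_epoch)[0]
        idx = idx[np.argsort(sub.volume_ids[idx] % P)]
        if strict:
            if idx.size != P or len(np.unique(sub.volume_ids[idx] % P)) != P:
                raise ValueError(
                    f"epoch {r} does not hold exactly one volume per PLD"
                )
        else:
            if len(np.unique(sub.plds[idx])) < 2:
                continue
        epochs.append(sub.take_volumes(idx))
    if not epochs:
        raise ValueError("no usable epochs")
    return epochs


def repeatability_cov(
    sub: AslSub,
    m0: ImageSeries,
    const: KineticConstants,
    gm: np.ndarray | None = None,
    strict: bool = True,
) -> float:
    """Coefficient of variation of per-epoch GM-mean CBF (sample std / mean).

    Each epoch is fitted independently with the same multi-start
    procedure as a full fit; lower CoV means higher repeatability.
    """
    if sub.acq.n_repeats < 2:
        raise ValueError("need >= 2 repetitions for repeatability")
    gm = gm if gm is not None else sub.gm_mask
    estimates = []
    for epoch in split_epochs(sub, strict=strict):
        fit = fit_dataset(epoch, m0, const, mask=gm)
        ok = gm.astype(bool) & fit.converged
        if not np.any(ok):
            raise ValueError("an epoch failed to fit anywhere in GM")
        estimates.append(float(fit.cbf[ok].mean()))
    estimates = np.asarray(estimates)
    mean = estimates.mean()
    if abs(mean) < 1e-12:
        return np.inf
    return float(np.std(estimates, ddof=1) / mean)


def repetition_curve(
    sub: AslSub,
    m0: ImageSeries,
    const: KineticConstants,
    gm: np.ndarray | None = None,
    denoiser: Callable[[AslSub], AslSub] | None = None,
    min_repeats: int = 2,
) -> list[dict]:
    """CBF-SNR as repetitions are removed stepwise, last acquired first.

    For ``k = n_repeats .. min_repeats`` the first ``k`` repetitions (in
    acquisition order) are retained, the optional denoiser applied, the
    kinetic model fitted over GM, and the CBF-SNR recorded.
    """
    if sub.acq.n_repeats < 2:
        raise ValueError("need >= 2 repetitions")
    gm = gm if gm is not None else sub.gm_mask
    P = sub.acq.n_plds
    rows = []
    for k in range(sub.acq.n_repeats, min_repeats - 1, -1):
        keep = np.where(sub.volume_ids < k * P)[0]
        sub_k = sub.take_volumes(keep)
        if denoiser is not None:
            sub_k = denoiser(sub_k)
        fit = fit_dataset(sub_k, m0, const, mask=gm)
        summary = snr_summary(fit, gm)
        rows.append({"n_reps": k, "cbf_snr": summary["cbf_snr"]})
    return rows


def poor_fit_count(fit: PerfusionFit, gm: np.ndarray) -> int:
    """GM voxels with z strictly below 2 (z = 2.0 exactly is not counted);
    non-converged voxels count as poorly fitted."""
    gm = gm.astype(bool)
    z = fit.z
    poor = (~fit.converged) | ~np.isfinite(z) | (z < 2.0)
    return int(np.sum(poor & gm))
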