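"""Noise removal: non-aggressive ICA regression, aCompCor and ENABLE.

All three methods return a :class:`DenoiseResult` whose cleaned series
shares the input grid.  The voxelwise temporal mean is removed before
any regression and added back afterwards, so denoising never shifts the
mean perfusion-weighted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import detrend

from aslica.preprocess import AslSub
from aslica.evaluate import quality_criteria

__all__ = ["DenoiseResult", "nonaggressive_regress", "acompcor", "enable_select"]


@dataclass
class DenoiseResult:
    """Outcome of one denoising run."""

    sub: AslSub
    method: str
    removed_components: list[int] = field(default_factory=list)
    removed_volumes: list[int] = field(default_factory=list)
    regressors: np.ndarray | None = None


def _to_matrix(sub: AslSub) -> tuple[np.ndarray, tuple]:
    shape = sub.data.shape
    return sub.data.reshape(-1, shape[3]).T.astype(float), shape


def _from_matrix(Y: np.ndarray, shape: tuple) -> np.ndarray:
    return Y.T.reshape(shape)


def nonaggressive_regress(
    sub: AslSub,
    mixing: np.ndarray,
    noise_idx: Sequence[int],
    aggressive: bool = False,
) -> DenoiseResult:
    """Regress noise components out of the series.

    Non-aggressive (default): fit *all* K component time courses jointly
    (``beta = pinv(M) @ Y``) and subtract only the noise partition
    (``M[:, noise] @ beta[noise]``), so variance shared between signal
    and noise components is retained.  Aggressive: project out the span
    of the noise columns alone.  ``noise_idx`` is 0-based.

    The mixing columns and the data are demeaned over time first; the
    voxelwise temporal mean is restored in the output.
    """
    Y, shape = _to_matrix(sub)
    T = Y.shape[0]
    M = np.asarray(mixing, dtype=float)
    if M.shape[0] != T:
        raise ValueError("mixing matrix row count must equal series length")
    K = M.shape[1]
    noise_idx = sorted(int(i) for i in noise_idx)
    if any(i < 0 or i >= K for i in noise_idx):
        raise ValueError(f"noise indices out of range 0..{K - 1}")

    mean = Y.mean(axis=0, keepdims=True)
    Yd = Y - mean
    Md = M - M.mean(axis=0, keepdims=True)

    if not noise_idx:
        cleaned = Y.copy()
    elif aggressive:
        Mn = Md[:, noise_idx]
        beta = np.linalg.pinv(Mn) @ Yd
        cleaned = mean + Yd - Mn @ beta
    else:
        if np.linalg.matrix_rank(Md) < K:
            import warnings

            warnings.warn(
                "rank-deficient mixing matrix: pseudo-inverse regression",
                RuntimeWarning,
                stacklevel=2,
            )
        beta = np.linalg.pinv(Md) @ Yd
        cleaned = mean + Yd - Md[:, noise_idx] @ beta[noise_idx, :]

    return DenoiseResult(
        sub=sub.with_data(_from_matrix(cleaned, shape)),
        method="ica-aggr" if aggressive else "ica-nonaggr",
        removed_components=noise_idx,
        regressors=Md[:, noise_idx] if noise_idx else None,
    )


def acompcor(
    sub: AslSub,
    noise_roi: np.ndarray,
    n_components: int = 5,
) -> DenoiseResult:
    """aCompCor: principal components of a WM/CSF noise ROI as nuisances.

    The ROI time series are linearly detrended, their top
    ``n_components`` principal component time courses extracted, and
    that nuisance subspace projected out of every voxel (aggressively),
    retaining each voxel's intercept and linear trend.
    """
    noise_roi = noise_roi.astype(bool)
    if not np.any(noise_roi):
        raise ValueError("empty noise ROI")
    if sub.gm_mask is not None and np.any(noise_roi & sub.gm_mask):
        raise ValueError("noise ROI must be disjoint from the GM mask")
    n_roi = int(noise_roi.sum())
    if n_components > n_roi:
        raise ValueError(f"ROI has {n_roi} voxels < n_components={n_components}")
    if n_components == 0:
        return DenoiseResult(sub=sub.with_data(sub.data.copy()), method="acompcor")

    Y, shape = _to_matrix(sub)
    T = Y.shape[0]

    roi_ts = sub.data[noise_roi, :].T.astype(float)  # T x Vroi
    roi_dt = detrend(roi_ts, axis=0, type="linear")
    # PCA over time courses: left singular vectors of the T x Vroi matrix
    U, s, _ = np.linalg.svd(roi_dt, full_matrices=False)
    pcs = U[:, :n_components]  # T x n, orthonormal

    # orthogonalize nuisances against intercept + linear trend, then
    # project them out of every voxel (trend and mean retained)
    t_norm = np.linspace(-1.0, 1.0, T)
    X = np.column_stack([np.ones(T), t_norm])
    Qx, _ = np.linalg.qr(X)
    pcs_orth = pcs - Qx @ (Qx.T @ pcs)
    Qp, Rp = np.linalg.qr(pcs_orth)
    keep = np.abs(np.diag(Rp)) > 1e-10
    Qp = Qp[:, keep]

    cleaned = Y - Qp @ (Qp.T @ Y)
    return DenoiseResult(
        sub=sub.with_data(_from_matrix(cleaned, shape)),
        method="acompcor",
        regressors=pcs,
    )


def enable_select(
    sub: AslSub,
    gm: np.ndarray | None = None,
    nonbrain: np.ndarray | None = None,
    outlier_z: float = 3.0,
) -> DenoiseResult:
    """ENABLE-style volume scrubbing by greedy backward elimination.

    At each step the composite quality of every admissible
    single-volume removal is scored: the four criteria (tCNR, proportion
    of GM voxels > 0, CoV, tSNR) are computed for each candidate subset,
    z-scored across the candidate pool (current subset included), and
    averaged with equal weight, the CoV entering negated.  The best
    removal is applied only when it is a genuine outlier: its composite
    gain must be positive and exceed the mean gain of the other
    candidates by ``outlier_z`` standard deviations.  (Without this gate
    the maximum over ~T exchangeable candidates beats the current subset
    almost surely, and the greedy chain scrubs statistically ordinary
    volumes.)  The search also stops when a volume's PLD would be left
    with no other volume (per-PLD retention floor).
    """
    gm = gm if gm is not None else sub.gm_mask
    nonbrain = nonbrain if nonbrain is not None else sub.nonbrain_mask
    if gm is None or not np.any(gm):
        raise ValueError("empty GM mask")
    if nonbrain is None or not np.any(nonbrain):
        raise ValueError("empty non-brain mask")
    if sub.n_volumes < sub.acq.n_plds:
        raise ValueError("fewer volumes than PLDs")

    current = sub
    removed: list[int] = []

    def crit_vec(s: AslSub) -> np.ndarray:
        q = quality_criteria(s, gm, nonbrain)
        return q.as_array()

    while current.n_volumes > 2:
        plds = current.plds
        # admissible: the volume's PLD retains at least one other volume
        counts = {p: int(np.sum(plds == p)) for p in np.unique(plds)}
        candidates = [i for i in range(current.n_volumes) if counts[plds[i]] >= 2]
        if not candidates:
            break

        pool = [crit_vec(current)]
        for i in candidates:
            keep = np.delete(np.arange(current.n_volumes), i)
            pool.append(crit_vec(current.take_volumes(keep)))
        pool_arr = np.vstack(pool)
        finite = np.isfinite(pool_arr)
        col_ok = finite.all(axis=0)
        mu = pool_arr[:, col_ok].mean(axis=0)
        sd = pool_arr[:, col_ok].std(axis=0, ddof=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        zed = np.zeros_like(pool_arr)
        zed[:, col_ok] = (pool_arr[:, col_ok] - mu) / sd
        # composite: tcnr + prop + tsnr - cov (criterion order of crit_vec)
        signs = np.array([1.0, 1.0, -1.0, 1.0])
        comp = (zed * signs).mean(axis=1)

        q_current = comp[0]
        deltas = comp[1:] - q_current
        best_j = int(np.argmax(deltas))
        if deltas[best_j] <= 1e-12:
            break
        others = np.delete(deltas, best_j)
        if others.size >= 2:
            spread = float(np.std(others, ddof=1))
            if spread > 1e-12 and (
                deltas[best_j] - float(np.mean(others))
            ) <= outlier_z * spread:
                break
        vol = candidates[best_j]
        removed.append(int(current.volume_ids[vol]))
        keep = np.delete(np.arange(current.n_volumes), vol)
        current = current.take_volumes(keep)

    return DenoiseResult(
        sub=current,
        method="enable",
        removed_volumes=sorted(removed),
    )
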