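"""Control-label subtraction, motion-parameter pairing and tissue masks.

The raw series alternates control and label volumes; the perfusion-weighted
difference (control - label, positive perfusion) follows the looped PLD
schedule: difference volume ``i`` sits at PLD index ``i % n_plds`` in
repetition ``i // n_plds``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation

from aslica.asl_io import AslAcquisition, ImageSeries, MotionParams

__all__ = ["AslSub", "subtract_pairs", "pair_motion_params", "tissue_masks"]


@dataclass
class AslSub:
    """4D subtracted (perfusion-weighted) series with masks and motion.

    ``data`` is X x Y x Z x T with ``T = n_plds * n_repeats`` (fewer after
    volume scrubbing); ``plds`` gives the PLD (seconds) of each retained
    volume and ``volume_ids`` its index in the original schedule.
    """

    data: np.ndarray
    acq: AslAcquisition
    plds: np.ndarray
    motion: np.ndarray | None = None
    gm_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    nonbrain_mask: np.ndarray | None = None
    affine: np.ndarray = None
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("AslSub data must be 4D")
        self.plds = np.asarray(self.plds, dtype=float)
        if self.plds.shape != (self.data.shape[3],):
            raise ValueError("one PLD per difference volume required")
        if self.affine is None:
            self.affine = np.eye(4)
        if self.volume_ids is None:
            self.volume_ids = np.arange(self.data.shape[3])
        else:
            self.volume_ids = np.asarray(self.volume_ids, dtype=int)
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.data.shape[3], 6):
                raise ValueError("motion must be T x 6 for the difference series")
        for name in ("gm_mask", "brain_mask", "nonbrain_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m).astype(bool)
                if m.shape != self.data.shape[:3]:
                    raise ValueError(f"{name} grid does not match series grid")
                setattr(self, name, m)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """T x V data matrix over ``mask`` (default: brain mask, else all)."""
        if mask is None:
            mask = self.brain_mask
        if mask is None:
            return self.data.reshape(-1, self.n_volumes).T
        return self.data[mask.astype(bool), :].T

    def with_data(self, data: np.ndarray, **kwargs) -> "AslSub":
        """Copy with replaced 4D data (and optionally other fields)."""
        return replace(self, data=np.asarray(data, dtype=np.float64), **kwargs)

    def take_volumes(self, idx: np.ndarray) -> "AslSub":
        """Sub-series keeping volumes ``idx`` (with PLDs, ids, motion rows)."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            data=self.data[..., idx],
            plds=self.plds[idx],
            motion=None if self.motion is None else self.motion[idx],
            volume_ids=self.volume_ids[idx],
        )


def subtract_pairs(raw: ImageSeries, acq: AslAcquisition,
                   motion: MotionParams | None = None) -> AslSub:
    """Pairwise control-label subtraction of an alternating raw series.

    The difference is control - label regardless of which comes first in
    the file (``acq.order`` decides).  When raw motion parameters are
    given they are pair-averaged onto the difference series.
    """
    nt = raw.nt
    if nt % 2:
        raise ValueError(f"raw series has odd volume count {nt}")
    if nt != acq.n_raw_volumes:
        raise ValueError(
            f"raw series has {nt} volumes but schedule implies {acq.n_raw_volumes}"
        )
    first = raw.data[..., 0::2].astype(np.float64)
    second = raw.data[..., 1::2].astype(np.float64)
    if acq.order == "control-first":
        diff = first - second
    else:
        diff = second - first
    paired = pair_motion_params(motion).params if motion is not None else None
    return AslSub(
        data=diff,
        acq=acq,
        plds=acq.pld_of_volume(np.arange(acq.n_diff_volumes)),
        motion=paired,
        affine=raw.affine,
        voxel_sizes=raw.voxel_sizes,
    )


def pair_motion_params(mp: MotionParams) -> MotionParams:
    """Average the motion parameters of each control/label pair.

    Row ``i`` of the result is the arithmetic mean of raw rows ``2i`` and
    ``2i + 1`` — the motion estimate carried by difference volume ``i``.
    """
    if mp.n_volumes % 2:
        raise ValueError(f"odd motion-parameter row count {mp.n_volumes}")
    arr = mp.params
    return MotionParams(params=0.5 * (arr[0::2] + arr[1::2]))


def tissue_masks(
    pve_gm: ImageSeries,
    brain: ImageSeries,
    pve_threshold: float = 0.70,
    dilate_vox: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """GM mask by PVE threshold plus a non-brain (noise reference) mask.

    GM mask is ``pve >= threshold`` (inclusive).  The non-brain mask is
    the complement of the brain mask dilated by ``dilate_vox`` voxels,
    excluding a 1-voxel image border, so partial brain signal cannot leak
    into the noise reference.
    """
    if not (0 < pve_threshold <= 1):
        raise ValueError("pve_threshold must lie in (0, 1]")
    pve = pve_gm.data[..., 0]
    if np.any((pve < 0) | (pve > 1)):
        raise ValueError("PVE values must lie in [0, 1]")
    brain_arr = brain.data[..., 0] > 0.5
    if pve.shape != brain_arr.shape:
        raise ValueError("PVE and brain mask grids differ")
    gm = pve >= pve_threshold
    dilated = binary_dilation(brain_arr, iterations=dilate_vox) if dilate_vox else brain_arr
    nonbrain = ~dilated
    border = np.zeros_like(nonbrain)
    border[1:-1, 1:-1, 1:-1] = True
    nonbrain &= border
    return gm, nonbrain
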