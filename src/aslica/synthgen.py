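"""Synthetic multi-PLD pCASL datasets with known ground truth.

The phantom is a concentric head: an ellipsoidal brain with a CSF
ventricle at the core, a WM interior, a GM shell near the surface, and
smooth partial-volume boundaries.  A simulated acquisition follows the
looped multi-PLD schedule (alternating control/label pairs); the label
volume is ``control - dM(PLD)`` with ``dM`` from the general kinetic
model at each voxel's PVE-weighted CBF/ATT.

Structured noise is planted as exact rank-1 space-time components
(motion-edge spikes, slow drift, CSF pulsation) plus i.i.d. thermal
noise.  Every component is written into the raw pair as +/- half onto
control/label, so pairwise subtraction reproduces the planted difference
contribution *exactly* — the generator output is its own ground truth in
the difference domain.

Background suppression is modeled as a single scalar attenuation of the
static tissue signal in control and label (default 0.1 of M0), leaving
``dM`` unscaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from aslica.asl_io import (
    AslAcquisition,
    ImageSeries,
    MotionParams,
    write_acquisition,
    write_motion_par,
    write_series,
)
from aslica.kinetics import KineticConstants, kinetic_signal

__all__ = [
    "TissuePhantom",
    "NoiseComponentSpec",
    "SyntheticTruth",
    "TissueTruth",
    "make_phantom",
    "noise_profile",
    "simulate_dataset",
    "write_dataset",
    "DATASET_FILES",
]

#: File set written by :func:`write_dataset`.
DATASET_FILES = [
    "raw.nii.gz",
    "m0.nii.gz",
    "pve_gm.nii.gz",
    "pve_wm.nii.gz",
    "pve_csf.nii.gz",
    "brain_mask.nii.gz",
    "edge_ribbon.nii.gz",
    "periventricular.nii.gz",
    "truth_cbf.nii.gz",
    "truth_att.nii.gz",
    "raw.par",
    "acq.yaml",
    "truth.json",
]


@dataclass
class TissuePhantom:
    """Tissue geometry: PVE maps, masks and the M0 calibration map."""

    pve_gm: np.ndarray
    pve_wm: np.ndarray
    pve_csf: np.ndarray
    brain_mask: np.ndarray
    edge_ribbon: np.ndarray
    periventricular: np.ndarray
    m0: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_sizes: tuple[float, float, float] = (3.4, 3.4, 4.5)

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.pve_gm.shape


@dataclass
class NoiseComponentSpec:
    """One planted noise component.

    Structured kinds (``motion-edge``, ``drift``, ``csf-pulsation``) are
    exact outer products ``amplitude * map x course`` added to the
    difference series.  The map is normalized to unit RMS over in-brain
    voxels and the course to unit maximum absolute value, so
    ``amplitude`` is the per-voxel RMS excursion (signal units) at the
    course peak.  ``thermal`` is i.i.d. Gaussian with sigma =
    ``amplitude`` (map and course unused).
    """

    kind: str
    amplitude: float
    spatial_map: np.ndarray | None = None
    time_course: np.ndarray | None = None

    KINDS = ("motion-edge", "drift", "csf-pulsation", "thermal")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")


@dataclass(frozen=True)
class TissueTruth:
    """Tissue-level ground truth (textbook defaults within the PLD range)."""

    gm_cbf: float = 60.0  # ml/100g/min
    wm_cbf: float = 20.0
    gm_att: float = 1.0  # s
    wm_att: float = 1.4


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    cbf: np.ndarray
    att: np.ndarray
    noise: list[NoiseComponentSpec]
    seed: int
    tissue: TissueTruth


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def _radial(grid: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius: 1.0 at the brain surface."""
    nx, ny, nz = grid
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = 0.42 * nx, 0.42 * ny, 0.42 * nz
    return np.sqrt(
        ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    )


def make_phantom(
    grid: tuple[int, int, int] = (32, 32, 8), seed: int = 0
) -> TissuePhantom:
    """Concentric GM-shell / WM-core / CSF-ventricle phantom.

    Deterministic for a fixed seed (the seed only textures the M0 map).
    Radial compartments (fractions of the brain radius): CSF ventricle
    < 0.30, WM 0.30-0.62, GM shell 0.62-1.0; hard compartments are
    smoothed into partial-volume fractions.
    """
    if min(grid) < 8:
        raise ValueError("each grid dimension must be >= 8 to host all compartments")
    r = _radial(grid)

    # trapezoid radial PVE profiles: linear transitions of width ``w``
    # around each compartment boundary, exact plateaus (fraction 1) inside
    w = 0.15

    def step(b: float) -> np.ndarray:
        return np.clip((r - b) / w + 0.5, 0.0, 1.0)

    s_csf, s_wm, s_out = step(0.30), step(0.62), step(1.0)
    pve_csf = 1.0 - s_csf
    pve_wm = s_csf - s_wm
    pve_gm = s_wm - s_out
    outside = r >= 1.0
    brain_mask = (pve_gm + pve_wm + pve_csf) > 0.5

    edge_ribbon = (r >= 0.97) & (r < 1.20)
    periventricular = (r >= 0.28) & (r < 0.42)

    rng = np.random.default_rng(seed)
    texture = gaussian_filter(rng.standard_normal(grid), 1.0)
    m0 = (1000.0 * pve_gm + 800.0 * pve_wm + 1300.0 * pve_csf) * (
        1.0 + 0.02 * texture
    )
    m0[~brain_mask & outside] *= 0.0
    m0 = np.maximum(m0, 0.0)

    return TissuePhantom(
        pve_gm=pve_gm,
        pve_wm=pve_wm,
        pve_csf=pve_csf,
        brain_mask=brain_mask,
        edge_ribbon=edge_ribbon,
        periventricular=periventricular,
        m0=m0,
    )


# ---------------------------------------------------------------------------
# Noise profiles
# ---------------------------------------------------------------------------

#: Default amplitudes (signal units; GM dM peaks near 9 with the default
#: phantom/constants).  Structured amplitudes sit at 5x the thermal sigma,
#: the regime where planted components are cleanly recoverable and
#: denoising benefit is measurable.
DEFAULT_AMPLITUDES = {
    "motion-edge": 10.0,
    "drift": 10.0,
    "csf-pulsation": 10.0,
    "thermal": 2.0,
}


def _unit_max(arr: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(arr))
    return arr / m if m > 0 else arr


def _unit_rms(arr: np.ndarray, domain: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(arr[domain] ** 2))
    return arr / rms if rms > 0 else arr


def noise_profile(
    name: str,
    phantom: TissuePhantom,
    acq: AslAcquisition,
    seed: int,
    amplitudes: dict | None = None,
    n_spikes: int = 3,
) -> list[NoiseComponentSpec]:
    """Build the planted noise set for a named profile.

    Profiles: ``clean`` (empty), ``motion`` (motion-edge + thermal),
    ``full`` (motion-edge + drift + CSF pulsation + thermal).
    """
    if name == "clean":
        return []
    amps = dict(DEFAULT_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)
    rng = np.random.default_rng(seed)
    T = acq.n_diff_volumes
    specs: list[NoiseComponentSpec] = []

    # motion-edge: smooth field on the boundary shell; subtraction errors at
    # the brain edge bleed into the outer GM rim, so the support is the
    # ribbon dilated inward/outward by two voxels
    from scipy.ndimage import binary_dilation

    shell = binary_dilation(phantom.edge_ribbon, iterations=1)
    field3d = gaussian_filter(
        shell * (1.0 + 0.5 * rng.standard_normal(phantom.grid)), 0.8
    )
    field3d *= shell
    course = np.zeros(T)
    spike_vols = rng.choice(T, size=min(n_spikes, T), replace=False)
    course[spike_vols] = rng.uniform(0.8, 1.2, size=spike_vols.size) * rng.choice(
        [-1.0, 1.0], size=spike_vols.size
    )
    specs.append(
        NoiseComponentSpec(
            kind="motion-edge",
            amplitude=amps["motion-edge"],
            spatial_map=_unit_rms(field3d, phantom.brain_mask),
            time_course=_unit_max(course),
        )
    )

    if name == "full":
        # drift: one cycle per scan on a saturating left-right field — a
        # low-order scanner-drift pattern that is as strong in the WM/CSF
        # core as at the cortex (tanh of the x offset, odd symmetry)
        nx = phantom.grid[0]
        x_off = np.arange(nx) - (nx - 1) / 2
        gradient = np.tanh(x_off / (0.12 * nx))[:, None, None] * np.ones(
            phantom.grid
        )
        drift_map = gradient * gaussian_filter(
            phantom.brain_mask.astype(float), 1.0
        )
        # cosine phase: one cycle per scan with no linear-trend component,
        # so trend-preserving cleanup methods see the full oscillation
        drift_course = np.cos(2 * np.pi * np.arange(T) / T)
        specs.append(
            NoiseComponentSpec(
                kind="drift",
                amplitude=amps["drift"],
                spatial_map=_unit_rms(drift_map, phantom.brain_mask),
                time_course=_unit_max(drift_course),
            )
        )
        # CSF pulsation: white course confined to the periventricular shell
        csf_map = gaussian_filter(
            phantom.periventricular
            * (1.0 + 0.5 * rng.standard_normal(phantom.grid)),
            0.8,
        )
        csf_map *= phantom.periventricular
        csf_course = rng.standard_normal(T)
        specs.append(
            NoiseComponentSpec(
                kind="csf-pulsation",
                amplitude=amps["csf-pulsation"],
                spatial_map=_unit_rms(csf_map, phantom.brain_mask),
                time_course=_unit_max(csf_course),
            )
        )

    if amps["thermal"] > 0:
        specs.append(NoiseComponentSpec(kind="thermal", amplitude=amps["thermal"]))
    return specs


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def truth_maps(
    phantom: TissuePhantom, tissue: TissueTruth
) -> tuple[np.ndarray, np.ndarray]:
    """PVE-weighted ground-truth CBF and ATT maps."""
    gm, wm = phantom.pve_gm, phantom.pve_wm
    cbf = tissue.gm_cbf * gm + tissue.wm_cbf * wm
    perf = gm + wm
    with np.errstate(invalid="ignore", divide="ignore"):
        att = np.where(
            perf > 1e-6,
            (tissue.gm_att * gm + tissue.wm_att * wm) / np.maximum(perf, 1e-6),
            1.0,
        )
    return cbf, att


def simulate_dataset(
    phantom: TissuePhantom,
    acq: AslAcquisition,
    tissue: TissueTruth = TissueTruth(),
    noise: list[NoiseComponentSpec] | None = None,
    seed: int = 0,
    const: KineticConstants | None = None,
    bg_suppression: float = 0.1,
    motion_jitter: tuple[float, float] = (0.002, 0.02),
    motion_spike: tuple[float, float] = (0.02, 0.5),
) -> tuple[ImageSeries, ImageSeries, MotionParams, SyntheticTruth]:
    """Simulate one raw alternating control/label acquisition.

    Returns ``(raw series, M0 volume, raw motion parameters, truth)``.
    The control volume is the background-suppressed static signal
    (``bg_suppression * M0``); the label volume subtracts the kinetic
    ``dM``.  Noise components are split +/- half across each pair so the
    difference domain carries them exactly.  Motion parameters hold
    baseline jitter plus spikes on the pairs where the motion-edge
    component spikes (``motion_spike`` = (radians, mm) peak scale).
    """
    noise = list(noise) if noise is not None else []
    if const is None:
        const = KineticConstants(tau=acq.tau)
    rng = np.random.default_rng(seed)
    grid = phantom.grid
    T = acq.n_diff_volumes

    cbf, att = truth_maps(phantom, tissue)
    m0a = phantom.m0 / const.lam

    # dM per (voxel, difference volume)
    plds = acq.pld_of_volume(np.arange(T))
    dm = kinetic_signal(
        plds[np.newaxis, np.newaxis, np.newaxis, :],
        cbf[..., np.newaxis],
        att[..., np.newaxis],
        const,
        m0a[..., np.newaxis],
    )

    # planted noise in the difference domain
    noise_diff = np.zeros(grid + (T,))
    for spec in noise:
        if spec.kind == "thermal":
            if spec.amplitude > 0:
                noise_diff += spec.amplitude * rng.standard_normal(grid + (T,))
        else:
            if spec.spatial_map is None or spec.time_course is None:
                raise ValueError(f"{spec.kind} component needs map and course")
            if spec.spatial_map.shape != grid:
                raise ValueError("noise spatial map grid mismatch")
            noise_diff += (
                spec.amplitude
                * spec.spatial_map[..., np.newaxis]
                * np.asarray(spec.time_course)[np.newaxis, np.newaxis, np.newaxis, :]
            )

    base = bg_suppression * phantom.m0
    raw = np.empty(grid + (2 * T,), dtype=np.float64)
    half = 0.5 * noise_diff
    control = base[..., np.newaxis] + half
    label = base[..., np.newaxis] - dm - half
    if acq.order == "control-first":
        raw[..., 0::2], raw[..., 1::2] = control, label
    else:
        raw[..., 0::2], raw[..., 1::2] = label, control

    # motion parameters: per-pair jitter (+ spikes aligned with the
    # motion-edge course), identical within a pair
    rot_j, tr_j = motion_jitter
    pair_mp = np.hstack(
        [
            rng.normal(0.0, rot_j, size=(T, 3)),
            rng.normal(0.0, tr_j, size=(T, 3)),
        ]
    )
    for spec in noise:
        if spec.kind == "motion-edge" and spec.time_course is not None:
            c = np.asarray(spec.time_course)
            pair_mp[:, :3] += motion_spike[0] * c[:, np.newaxis]
            pair_mp[:, 3:] += motion_spike[1] * c[:, np.newaxis]
    raw_mp = np.repeat(pair_mp, 2, axis=0)

    affine = np.diag(list(phantom.voxel_sizes) + [1.0])
    series = ImageSeries(raw, affine, phantom.voxel_sizes)
    m0_img = ImageSeries(phantom.m0, affine, phantom.voxel_sizes)
    truth = SyntheticTruth(cbf=cbf, att=att, noise=noise, seed=seed, tissue=tissue)
    return series, m0_img, MotionParams(raw_mp), truth


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------


def write_dataset(
    directory: str | Path,
    phantom: TissuePhantom,
    acq: AslAcquisition,
    raw: ImageSeries,
    m0: ImageSeries,
    motion: MotionParams,
    truth: SyntheticTruth,
) -> Path:
    """Write the full simulated dataset; re-readable via :mod:`aslica.asl_io`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff, vs = raw.affine, raw.voxel_sizes

    write_series(raw, directory / "raw.nii.gz")
    write_series(m0, directory / "m0.nii.gz")
    for name, arr in [
        ("pve_gm", phantom.pve_gm),
        ("pve_wm", phantom.pve_wm),
        ("pve_csf", phantom.pve_csf),
        ("brain_mask", phantom.brain_mask.astype(np.float32)),
        ("edge_ribbon", phantom.edge_ribbon.astype(np.float32)),
        ("periventricular", phantom.periventricular.astype(np.float32)),
        ("truth_cbf", truth.cbf),
        ("truth_att", truth.att),
    ]:
        write_series(ImageSeries(arr, aff, vs), directory / f"{name}.nii.gz")
    write_motion_par(motion, directory / "raw.par")
    write_acquisition(acq, directory / "acq.yaml")

    payload = {
        "seed": int(truth.seed),
        "tissue": {
            "gm_cbf": truth.tissue.gm_cbf,
            "wm_cbf": truth.tissue.wm_cbf,
            "gm_att": truth.tissue.gm_att,
            "wm_att": truth.tissue.wm_att,
        },
        "noise": [
            {
                "kind": s.kind,
                "amplitude": float(s.amplitude),
                "time_course": (
                    None
                    if s.time_course is None
                    else [float(v) for v in np.asarray(s.time_course)]
                ),
            }
            for s in truth.noise
        ],
    }
    (directory / "truth.json").write_text(json.dumps(payload, indent=2))
    return directory
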