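"""Readers and writers for every on-disk artifact the pipeline touches.

File dialects
-------------
* Images: NIfTI-1 (``.nii`` / ``.nii.gz``), intensities stored float32.
* Motion parameters: whitespace-delimited text, 6 columns per volume —
  3 rotations (radians) then 3 translations (mm), the rigid-body
  convention of MCFLIRT ``.par`` files.
* Component labels: FIX "hand-labels" dialect.  The final line of the file
  is the bracketed, comma-separated, **1-based** list of noise-component
  indices, e.g. ``[2, 3]``.
* Acquisition descriptor: YAML with keys ``plds_s``, ``tau_s``,
  ``n_repeats``, ``order``, ``tr_s``.
* Metric reports: CSV, one row per (dataset, method).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AslAcquisition",
    "ImageSeries",
    "MotionParams",
    "ComponentLabels",
    "read_series",
    "write_series",
    "read_motion_par",
    "write_motion_par",
    "read_labels",
    "write_labels",
    "read_acquisition",
    "write_acquisition",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

#: Column set of the per-(dataset, method) metric report.
REPORT_COLUMNS = [
    "dataset",
    "method",
    "cbf_mean",
    "cbf_variance",
    "cbf_snr",
    "att_mean",
    "att_variance",
    "att_snr",
]


@dataclass(frozen=True)
class AslAcquisition:
    """Multi-PLD pCASL acquisition schedule.

    The PLD list is looped: difference volume ``i`` was acquired at
    ``plds[i % len(plds)]`` during repetition ``i // len(plds)``.

    Parameters
    ----------
    plds : strictly increasing post-labeling delays, seconds.
    tau : label duration, seconds.
    n_repeats : repetitions of the PLD loop.
    order : ``"control-first"`` or ``"label-first"`` volume ordering.
    tr : repetition time, seconds.
    """

    plds: tuple[float, ...]
    tau: float = 1.8
    n_repeats: int = 6
    order: str = "control-first"
    tr: float = 5.386

    def __post_init__(self) -> None:
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))
        if len(self.plds) < 1 or any(
            b <= a for a, b in zip(self.plds, self.plds[1:])
        ):
            raise ValueError("plds must be non-empty and strictly increasing")
        if self.tau <= 0:
            raise ValueError("label duration tau must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.order not in ("control-first", "label-first"):
            raise ValueError(f"unknown volume ordering {self.order!r}")

    @property
    def n_plds(self) -> int:
        return len(self.plds)

    @property
    def n_diff_volumes(self) -> int:
        """Total difference volumes = n_plds * n_repeats."""
        return self.n_plds * self.n_repeats

    @property
    def n_raw_volumes(self) -> int:
        return 2 * self.n_diff_volumes

    def pld_of_volume(self, i: int | np.ndarray) -> np.ndarray:
        """PLD (seconds) of difference volume(s) ``i`` under the looped schedule."""
        return np.asarray(self.plds)[np.asarray(i) % self.n_plds]

    def pld_indices(self) -> np.ndarray:
        """Per-difference-volume PLD index, length ``n_diff_volumes``."""
        return np.arange(self.n_diff_volumes) % self.n_plds


DEFAULT_ACQUISITION = AslAcquisition(plds=(0.4, 0.8, 1.2, 1.6, 2.0))


@dataclass
class ImageSeries:
    """A 3D/4D image: intensity array plus grid geometry.

    ``data`` always carries 4 axes; a 3D image is promoted to ``nt = 1``.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_sizes: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[..., np.newaxis]
        if arr.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got {arr.ndim}D")
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def same_grid(self, other: "ImageSeries", atol: float = 1e-4) -> bool:
        return self.grid == other.grid and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class MotionParams:
    """Rigid-body motion parameters, one 6-vector per volume.

    Columns 0-2 are rotations (radians), 3-5 translations (mm).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.params, dtype=float))
        if arr.shape[1] != 6:
            raise ValueError(f"motion parameters need 6 columns, got {arr.shape[1]}")
        self.params = arr

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class ComponentLabels:
    """Per-component signal/noise calls, optionally with signal probabilities."""

    labels: list[str]
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"signal", "noise"}
        if bad:
            raise ValueError(f"labels must be 'signal' or 'noise', got {bad}")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.labels),):
                raise ValueError("probabilities length must match labels")
            if np.any((p < 0) | (p > 1)):
                raise ValueError("probabilities must lie in [0, 1]")
            self.probabilities = p

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def noise_indices(self) -> list[int]:
        """0-based indices of noise components."""
        return [i for i, lab in enumerate(self.labels) if lab == "noise"]

    @property
    def signal_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == "signal"]

    def as_binary(self) -> np.ndarray:
        """1 for signal, 0 for noise."""
        return np.array([1 if lab == "signal" else 0 for lab in self.labels])


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------


def read_series(path: str | Path) -> ImageSeries:
    """Read a 3D/4D NIfTI image; 3D inputs become single-volume series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim > 4:
        raise ValueError(f"{path}: images with more than 4 dimensions unsupported")
    if img.ndim < 3:
        raise ValueError(f"{path}: expected a 3D or 4D image, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    return ImageSeries(data=data, affine=img.affine, voxel_sizes=tuple(float(z) for z in zooms))


def write_series(series: ImageSeries, path: str | Path) -> Path:
    """Write an :class:`ImageSeries` as float32 NIfTI-1; 1-volume series written 3D."""
    path = Path(path)
    data = series.data
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_sizes) + ((1.0,) if img.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Motion parameters
# ---------------------------------------------------------------------------


def read_motion_par(path: str | Path, n_volumes: int | None = None) -> MotionParams:
    """Read a 6-column whitespace-delimited motion-parameter file.

    When ``n_volumes`` is given the row count is checked against it.
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    if n_volumes is not None and arr.shape[0] != n_volumes:
        raise ValueError(
            f"{path}: {arr.shape[0]} rows but series has {n_volumes} volumes"
        )
    return MotionParams(params=arr)


def write_motion_par(mp: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(str(path), mp.params, fmt="%.10g")
    return path


# ---------------------------------------------------------------------------
# Component labels (FIX hand-labels dialect)
# ---------------------------------------------------------------------------


def write_labels(labels: ComponentLabels, path: str | Path) -> Path:
    """Write labels in the FIX hand-labels dialect.

    One ``index, label[, probability]`` line per component, then a final
    line holding the bracketed 1-based list of noise indices.
    """
    path = Path(path)
    lines = []
    for i, lab in enumerate(labels.labels):
        if labels.probabilities is not None:
            lines.append(f"{i + 1}, {lab}, {labels.probabilities[i]:.6f}")
        else:
            lines.append(f"{i + 1}, {lab}")
    noise_1based = [i + 1 for i in labels.noise_indices]
    lines.append("[" + ", ".join(str(i) for i in noise_1based) + "]")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_labels(path: str | Path) -> ComponentLabels:
    """Read a FIX-dialect label file (inverse of :func:`write_labels`).

    Only the final bracketed noise list is authoritative; per-component
    lines, when present, supply the component count and probabilities.
    """
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty label file")
    lines = text.splitlines()
    final = lines[-1].strip()
    m = re.fullmatch(r"\[\s*((?:\d+\s*,\s*)*\d+)?\s*\]", final)
    if m is None:
        raise ValueError(f"{path}: final line is not a bracketed index list: {final!r}")
    noise_1based = (
        [int(tok) for tok in m.group(1).split(",")] if m.group(1) else []
    )

    n_components = 0
    probs: dict[int, float] = {}
    for line in lines[:-1]:
        parts = [p.strip() for p in line.split(",")]
        if not parts or not parts[0].isdigit():
            continue
        idx = int(parts[0])
        n_components = max(n_components, idx)
        if len(parts) >= 3:
            probs[idx] = float(parts[2])
    if n_components == 0:
        n_components = max(noise_1based, default=0)
    if any(i < 1 or i > n_components for i in noise_1based):
        raise ValueError(f"{path}: noise index out of range 1..{n_components}")

    noise_set = set(noise_1based)
    lab = ["noise" if i + 1 in noise_set else "signal" for i in range(n_components)]
    probabilities = None
    if probs and len(probs) == n_components:
        probabilities = np.array([probs[i + 1] for i in range(n_components)])
    return ComponentLabels(labels=lab, probabilities=probabilities)


# ---------------------------------------------------------------------------
# Acquisition descriptor
# ---------------------------------------------------------------------------


def write_acquisition(acq: AslAcquisition, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "plds_s": [float(p) for p in acq.plds],
        "tau_s": float(acq.tau),
        "n_repeats": int(acq.n_repeats),
        "order": acq.order,
        "tr_s": float(acq.tr),
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_acquisition(path: str | Path) -> AslAcquisition:
    payload = yaml.safe_load(Path(path).read_text())
    try:
        return AslAcquisition(
            plds=tuple(payload["plds_s"]),
            tau=float(payload["tau_s"]),
            n_repeats=int(payload["n_repeats"]),
            order=payload.get("order", "control-first"),
            tr=float(payload.get("tr_s", 5.386)),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"{path}: missing acquisition key {exc}") from exc


# ---------------------------------------------------------------------------
# Metric reports
# ---------------------------------------------------------------------------


def write_report(metrics: pd.DataFrame | Sequence[dict], path: str | Path) -> Path:
    """Write the per-(dataset, method) metric table as CSV.

    Accepts any frame containing at least :data:`REPORT_COLUMNS`; extra
    columns (poor-fit counts, repeatability) are preserved after them.
    """
    path = Path(path)
    df = pd.DataFrame(metrics)
    if df.empty:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    extra = [c for c in df.columns if c not in REPORT_COLUMNS]
    df = df[REPORT_COLUMNS + extra]
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
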