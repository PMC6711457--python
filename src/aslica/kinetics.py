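"""Voxelwise multi-PLD CBF/ATT estimation under the pCASL general kinetic model.

Model
-----
Single-compartment (Buxton) general kinetic model for pseudo-continuous
labeling of duration ``tau``, read out at ``t = tau + PLD`` after label
onset.  With apparent tissue relaxation ``1/T1app = 1/T1t + f/lambda``
(``f`` in ml/g/s) the difference signal is

* ``0``                                                        for ``t < att``
* ``2 m0a alpha f T1app exp(-att/T1b) (1 - exp(-(t-att)/T1app))``
  for ``att <= t < att + tau``
* ``2 m0a alpha f T1app exp(-att/T1b) exp(-(t-att-tau)/T1app)
  (1 - exp(-tau/T1app))``                                      for ``t >= att + tau``

continuous in ``t`` at both breakpoints.  CBF is carried in the
conventional ml/100g/min units throughout the public API and converted to
ml/g/s (divide by 6000) inside the model.

Fitting
-------
:class:`KineticFitter` is a scikit-learn-style estimator over a voxel
batch.  It profiles ATT on a dense grid (``f`` solved per grid point by
iterated linear least squares, exact up to the weak ``T1app(f)``
nonlinearity) and polishes the best grid point with damped Gauss-Newton
steps — equivalent to multi-start nonlinear least squares but vectorized
across voxels.  :func:`fit_voxel` is the scalar reference path using
``scipy.optimize.least_squares`` with an explicit ATT multi-start, kept
as an independent cross-check of the batched fitter.

Uncertainty is Jacobian-based: ``cov = s^2 (J'J)^-1`` with ``s^2`` the
residual variance; ``z = CBF / sd(CBF)`` is the goodness-of-fit marker
(voxels with z below 2 are counted as poorly fitted downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.ndimage import gaussian_filter

from aslica.asl_io import AslAcquisition, ImageSeries, write_series

__all__ = [
    "KineticConstants",
    "PerfusionFit",
    "KineticFitter",
    "kinetic_signal",
    "fit_voxel",
    "fit_dataset",
    "ATT_STARTS",
    "F_BOUNDS",
    "ATT_BOUNDS",
]

#: ATT multi-start grid (seconds) for the scalar reference fit.
ATT_STARTS = (0.3, 0.7, 1.1, 1.5, 1.9)
#: CBF bounds, ml/100g/min.
F_BOUNDS = (0.0, 300.0)
#: ATT bounds, seconds.
ATT_BOUNDS = (0.1, 3.0)

_F_TO_SI = 1.0 / 6000.0  # ml/100g/min -> ml/g/s


@dataclass(frozen=True)
class KineticConstants:
    """Physiological constants of the kinetic model (3 T consensus defaults).

    T1b/T1t are blood/tissue longitudinal relaxation times (s), ``alpha``
    the labeling efficiency, ``lam`` the blood-tissue partition
    coefficient (ml/g) and ``tau`` the label duration (s).
    """

    T1b: float = 1.65
    T1t: float = 1.3
    alpha: float = 0.85
    lam: float = 0.9
    tau: float = 1.8

    def __post_init__(self) -> None:
        for name in ("T1b", "T1t", "alpha", "lam", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha <= 1.2) or not (0 < self.lam <= 1.2):
            raise ValueError("alpha and lam must lie in (0, 1.2]")


@dataclass
class PerfusionFit:
    """Voxelwise fit result: CBF/ATT maps with uncertainty.

    All maps share the source grid; voxels outside the fitted mask are NaN.
    ``z = cbf / sd_cbf`` where converged, NaN elsewhere.
    """

    cbf: np.ndarray
    att: np.ndarray
    sd_cbf: np.ndarray
    sd_att: np.ndarray
    z: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    affine: np.ndarray | None = None
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = self.affine if self.affine is not None else np.eye(4)
        for name, arr in [
            ("cbf", self.cbf),
            ("att", self.att),
            ("cbf_sd", self.sd_cbf),
            ("att_sd", self.sd_att),
            ("zstat", self.z),
            ("residual", self.residual),
        ]:
            write_series(
                ImageSeries(arr.astype(np.float32), aff, self.voxel_sizes),
                directory / f"{name}.nii.gz",
            )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def kinetic_signal(
    pld: float | np.ndarray,
    f: float | np.ndarray,
    att: float | np.ndarray,
    const: KineticConstants = KineticConstants(),
    m0a: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Difference-signal prediction of the general kinetic model.

    Parameters broadcast against each other; ``f`` is CBF in ml/100g/min,
    ``pld`` and ``att`` in seconds, ``m0a`` the arterial magnetization in
    the same (arbitrary) units as the returned signal.
    """
    pld = np.asarray(pld, dtype=float)
    if np.any(pld < 0):
        raise ValueError("pld must be non-negative")
    f = np.asarray(f, dtype=float)
    att = np.asarray(att, dtype=float)
    m0a = np.asarray(m0a, dtype=float)

    f_si = f * _F_TO_SI
    t = const.tau + pld
    inv_t1app = 1.0 / const.T1t + f_si / const.lam
    t1app = 1.0 / inv_t1app
    amp = 2.0 * m0a * const.alpha * f_si * t1app * np.exp(-att / const.T1b)

    pld, f_si, att, amp, t1app, t = np.broadcast_arrays(
        pld, f_si, att, amp, t1app, t
    )
    out = np.zeros_like(t, dtype=float)

    during = (t >= att) & (t < att + const.tau)
    out[during] = amp[during] * -np.expm1(-(t[during] - att[during]) / t1app[during])

    after = t >= att + const.tau
    out[after] = (
        amp[after]
        * np.exp(-(t[after] - att[after] - const.tau) / t1app[after])
        * -np.expm1(-const.tau / t1app[after])
    )
    return out


def _jacobian(pld, f, att, const, m0a):
    """Analytic-by-differences Jacobian d(signal)/d(f, att), shape (..., 2)."""
    eps_f = 1e-4 * max(abs(float(np.max(np.atleast_1d(f)))), 1.0)
    eps_a = 1e-5
    d_f = (
        kinetic_signal(pld, f + eps_f, att, const, m0a)
        - kinetic_signal(pld, f - eps_f, att, const, m0a)
    ) / (2 * eps_f)
    d_a = (
        kinetic_signal(pld, f, att + eps_a, const, m0a)
        - kinetic_signal(pld, f, att - eps_a, const, m0a)
    ) / (2 * eps_a)
    return np.stack([d_f, d_a], axis=-1)


# ---------------------------------------------------------------------------
# Scalar reference fit (multi-start nonlinear least squares)
# ---------------------------------------------------------------------------


def fit_voxel(
    signal: np.ndarray,
    plds: np.ndarray,
    const: KineticConstants = KineticConstants(),
    m0a: float = 1.0,
    att_starts: tuple[float, ...] = ATT_STARTS,
) -> tuple[float, float, float, float, float, bool]:
    """Fit one voxel's per-volume signal by multi-start nonlinear least squares.

    ``signal`` holds one observation per volume (repeats enter as replicate
    observations, not pre-averaged), ``plds`` the matching PLD per volume.

    Returns ``(f, att, sd_f, sd_att, z, converged)``.  An all-zero signal
    returns ``f = 0`` flagged non-converged (non-informative) rather than
    raising.
    """
    signal = np.asarray(signal, dtype=float)
    plds = np.asarray(plds, dtype=float)
    if len(np.unique(plds)) < 2:
        raise ValueError("need >= 2 distinct PLDs to fit f and att")
    if signal.shape != plds.shape:
        raise ValueError("signal and plds must align")
    if not np.any(signal != 0):
        return 0.0, ATT_BOUNDS[0], np.nan, np.nan, np.nan, False

    def resid(theta):
        return kinetic_signal(plds, theta[0], theta[1], const, m0a) - signal

    best = None
    f0 = max(min(np.mean(np.abs(signal)) / max(m0a * 1e-3, 1e-12), 200.0), 1.0)
    for att0 in att_starts:
        sol = least_squares(
            resid,
            x0=[f0, att0],
            bounds=([F_BOUNDS[0], ATT_BOUNDS[0]], [F_BOUNDS[1], ATT_BOUNDS[1]]),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    f, att = best.x
    r = best.fun
    dof = max(signal.size - 2, 1)
    s2 = float(r @ r) / dof
    J = _jacobian(plds, f, att, const, m0a)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        sd_f = float(np.sqrt(max(cov[0, 0], 0.0)))
        sd_att = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        sd_f = sd_att = np.nan
    z = f / sd_f if sd_f and np.isfinite(sd_f) and sd_f > 0 else np.nan
    converged = bool(best.success and np.isfinite(sd_f))
    return float(f), float(att), sd_f, sd_att, float(z), converged


# ---------------------------------------------------------------------------
# Batched fitter
# ---------------------------------------------------------------------------


class KineticFitter:
    """Batched CBF/ATT estimator over voxels (scikit-learn style).

    Parameters
    ----------
    const : kinetic constants.
    att_grid_step : ATT profiling grid step, seconds.
    n_polish : damped Gauss-Newton polish iterations after the grid stage.
    t1app_iters : fixed-point iterations absorbing the ``T1app(f)``
        dependence into the per-grid-point linear solve for ``f``.

    Attributes (after :meth:`fit`)
    ------------------------------
    cbf_, att_, sd_cbf_, sd_att_, z_, residual_, converged_ : 1D arrays
        over the voxel batch.
    """

    def __init__(
        self,
        const: KineticConstants = KineticConstants(),
        att_grid_step: float = 0.02,
        n_polish: int = 4,
        t1app_iters: int = 2,
    ) -> None:
        self.const = const
        self.att_grid_step = att_grid_step
        self.n_polish = n_polish
        self.t1app_iters = t1app_iters

    def get_params(self, deep: bool = True) -> dict:
        return {
            "const": self.const,
            "att_grid_step": self.att_grid_step,
            "n_polish": self.n_polish,
            "t1app_iters": self.t1app_iters,
        }

    def set_params(self, **params) -> "KineticFitter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------

    def _unit_curves(self, plds: np.ndarray, att_grid: np.ndarray, f_ref: np.ndarray):
        """Model curves at f_ref for every (att grid point, PLD), m0a = 1."""
        return kinetic_signal(
            plds[np.newaxis, :], f_ref[:, np.newaxis], att_grid[:, np.newaxis],
            self.const, 1.0,
        )

    def fit(self, Y: np.ndarray, plds: np.ndarray, m0a: np.ndarray | float = 1.0):
        """Fit every column-voxel of ``Y`` (T x V observations).

        ``m0a`` is scalar or per-voxel (length V).  Signals are divided by
        ``m0a`` so the model is fit with unit arterial magnetization.
        """
        Y = np.asarray(Y, dtype=float)
        plds = np.asarray(plds, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != plds.size:
            raise ValueError("Y must be T x V with one PLD per row")
        if len(np.unique(plds)) < 2:
            raise ValueError("need >= 2 distinct PLDs")
        T, V = Y.shape
        m0a_arr = np.broadcast_to(np.asarray(m0a, dtype=float), (V,)).copy()
        bad_m0 = ~(m0a_arr > 0)
        m0a_arr[bad_m0] = 1.0
        Yn = Y / m0a_arr  # unit-m0a signal

        att_grid = np.arange(
            ATT_BOUNDS[0], ATT_BOUNDS[1] + 1e-9, self.att_grid_step
        )
        G = att_grid.size

        # profile f linearly per att grid point, iterating the T1app(f) link
        f_ref = np.full(G, 50.0)
        sig_mean = Yn.mean(axis=0)
        f_grid = np.empty((G, V))
        for _ in range(self.t1app_iters + 1):
            C = self._unit_curves(plds, att_grid, f_ref)  # G x T at f_ref
            # linearize: signal ~ (C / f_ref) * f  (exact if T1app fixed)
            B = C / np.maximum(f_ref[:, np.newaxis], 1e-9)  # per-unit-f basis
            num = B @ Yn  # G x V
            den = np.sum(B * B, axis=1)[:, np.newaxis]  # G x 1
            f_grid = np.clip(num / np.maximum(den, 1e-30), *F_BOUNDS)
            # next T1app linearization point: typical fitted f per att
            f_typ = np.median(f_grid, axis=1)
            f_ref = np.clip(np.where(f_typ > 1e-3, f_typ, 50.0), 1.0, F_BOUNDS[1])

        # SSE per (grid, voxel) without materializing G x T x V:
        # SSE = ||Yn||^2 - 2 f (B.Yn) + f^2 ||B||^2
        yn2 = np.sum(Yn * Yn, axis=0)[np.newaxis, :]
        C = self._unit_curves(plds, att_grid, f_ref)
        B = C / np.maximum(f_ref[:, np.newaxis], 1e-9)
        num = B @ Yn
        den = np.sum(B * B, axis=1)[:, np.newaxis]
        sse = yn2 - 2.0 * f_grid * num + f_grid**2 * den
        best = np.argmin(sse, axis=0)  # per voxel
        att = att_grid[best]
        f = np.clip(f_grid[best, np.arange(V)], *F_BOUNDS)

        # damped Gauss-Newton polish, vectorized over voxels
        resid = kinetic_signal(
            plds[np.newaxis, :], f[:, np.newaxis], att[:, np.newaxis], self.const, 1.0
        ) - Yn.T  # V x T
        sse_cur = np.sum(resid * resid, axis=1)
        for _ in range(self.n_polish):
            J = _jacobian(
                plds[np.newaxis, :], f[:, np.newaxis], att[:, np.newaxis],
                self.const, 1.0,
            )  # V x T x 2
            JtJ = np.einsum("vti,vtj->vij", J, J)
            Jtr = np.einsum("vti,vt->vi", J, resid)
            # Levenberg damping for near-singular voxels
            lam = 1e-8 * np.trace(JtJ, axis1=1, axis2=2)[:, None, None] + 1e-30
            A = JtJ + lam * np.eye(2)[np.newaxis]
            try:
                step = np.linalg.solve(A, Jtr[..., np.newaxis])[..., 0]
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                break
            f_new = np.clip(f - step[:, 0], *F_BOUNDS)
            att_new = np.clip(att - step[:, 1], *ATT_BOUNDS)
            resid_new = kinetic_signal(
                plds[np.newaxis, :], f_new[:, np.newaxis], att_new[:, np.newaxis],
                self.const, 1.0,
            ) - Yn.T
            sse_new = np.sum(resid_new * resid_new, axis=1)
            improved = sse_new <= sse_cur
            f = np.where(improved, f_new, f)
            att = np.where(improved, att_new, att)
            resid = np.where(improved[:, np.newaxis], resid_new, resid)
            sse_cur = np.where(improved, sse_new, sse_cur)

        # Jacobian-based uncertainty (on the unit-m0a scale == f scale)
        J = _jacobian(
            plds[np.newaxis, :], f[:, np.newaxis], att[:, np.newaxis], self.const, 1.0
        )
        JtJ = np.einsum("vti,vtj->vij", J, J)
        dof = max(T - 2, 1)
        s2 = sse_cur / dof
        det = JtJ[:, 0, 0] * JtJ[:, 1, 1] - JtJ[:, 0, 1] * JtJ[:, 1, 0]
        ok = det > 1e-30
        inv00 = np.where(ok, JtJ[:, 1, 1] / np.where(ok, det, 1.0), np.nan)
        inv11 = np.where(ok, JtJ[:, 0, 0] / np.where(ok, det, 1.0), np.nan)
        sd_f = np.sqrt(np.maximum(s2 * inv00, 0.0))
        sd_att = np.sqrt(np.maximum(s2 * inv11, 0.0))

        informative = np.any(Yn != 0, axis=0)
        converged = informative & ok & np.isfinite(sd_f) & ~bad_m0
        f = np.where(informative, f, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(converged & (sd_f > 0), f / sd_f, np.nan)

        self.cbf_ = f
        self.att_ = att
        self.sd_cbf_ = np.where(converged, sd_f, np.nan)
        self.sd_att_ = np.where(converged, sd_att, np.nan)
        self.z_ = z
        self.residual_ = np.sqrt(sse_cur / max(T, 1))
        self.converged_ = converged
        return self


# ---------------------------------------------------------------------------
# Dataset-level fit
# ---------------------------------------------------------------------------


def fit_dataset(
    sub,
    m0: ImageSeries,
    const: KineticConstants = KineticConstants(),
    mask: np.ndarray | None = None,
    m0_smooth_sigma_vox: float = 1.0,
    fitter: KineticFitter | None = None,
) -> PerfusionFit:
    """Fit CBF/ATT over a masked 4D difference series.

    ``sub`` is an :class:`aslica.preprocess.AslSub`.  ``m0a`` is the
    (optionally smoothed) M0 divided by the partition coefficient.
    ``mask`` defaults to the brain mask; pass the GM mask to restrict
    quantification.  Voxels with non-positive M0 are flagged and excluded.
    """
    data = sub.data
    plds = sub.plds
    if m0.grid != data.shape[:3]:
        raise ValueError("M0 grid does not match series grid")
    if mask is None:
        mask = sub.brain_mask
    mask = mask.astype(bool)

    m0_map = m0.data[..., 0].astype(float)
    if m0_smooth_sigma_vox > 0:
        sm = gaussian_filter(m0_map * mask, m0_smooth_sigma_vox)
        norm = gaussian_filter(mask.astype(float), m0_smooth_sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            m0_map = np.where(norm > 1e-6, sm / norm, m0_map)
    m0a = m0_map / const.lam

    vox = np.where(mask.reshape(-1))[0]
    Y = data.reshape(-1, data.shape[3]).T[:, vox]
    m0a_v = m0a.reshape(-1)[vox]

    fitter = fitter if fitter is not None else KineticFitter(const=const)
    fitter.fit(Y, plds, m0a_v)

    shape = data.shape[:3]

    def unflatten(values, fill=np.nan):
        out = np.full(int(np.prod(shape)), fill, dtype=float)
        out[vox] = values
        return out.reshape(shape)

    return PerfusionFit(
        cbf=unflatten(fitter.cbf_),
        att=unflatten(fitter.att_),
        sd_cbf=unflatten(fitter.sd_cbf_),
        sd_att=unflatten(fitter.sd_att_),
        z=unflatten(fitter.z_),
        residual=unflatten(fitter.residual_),
        converged=unflatten(fitter.converged_.astype(float), fill=0.0).astype(bool),
        affine=sub.affine,
        voxel_sizes=sub.voxel_sizes,
    )
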