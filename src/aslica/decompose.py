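"""Single-subject spatial ICA with automatic model-order estimation.

The subtracted series is arranged as a T x V matrix over in-brain voxels
and double-centered (per-voxel temporal mean, then per-volume spatial
mean).  Model order is chosen by the Laplace approximation to the
probabilistic-PCA evidence on the covariance eigenspectrum (Minka's
criterion, with the exact finite-sample terms), clamped to [2, T-2].
The decomposition itself is symmetric fixed-point ICA with the logcosh
contrast on the PCA-whitened spatial sources, restarted several times
and keeping the run with the highest total negentropy.

Conventions: spatial maps are z-scored over voxels (mean 0, variance 1),
mixing-matrix columns are unit-variance over time, components are ordered
by descending explained variance, and each map's sign is chosen so its
skewness is non-negative.  Per-component amplitudes are kept so that
``mean fields + mixing @ diag(amplitudes) @ maps`` reproduces the PCA
reconstruction at the retained order exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from aslica.asl_io import ImageSeries, write_series
from aslica.preprocess import AslSub

__all__ = ["SpatialICA", "estimate_dimensionality", "IcaDecomposition"]


# ---------------------------------------------------------------------------
# Model order: Laplace/PPCA evidence (Minka)
# ---------------------------------------------------------------------------


def _laplace_evidence(spectrum: np.ndarray, rank: int, n_samples: int) -> float:
    """Log evidence of a rank-``rank`` probabilistic PCA model.

    ``spectrum`` holds the descending eigenvalues of the d x d data
    covariance estimated from ``n_samples`` observations.
    """
    lam = np.asarray(spectrum, dtype=float)
    d = lam.size
    k = rank
    N = n_samples
    if k >= d:
        raise ValueError("rank must be < dimension")
    sigma2 = lam[k:].mean()
    if sigma2 <= 0 or np.any(lam[:k] <= 0):
        return -np.inf

    # log p(U): uniform prior over the Stiefel manifold
    j = np.arange(1, k + 1)
    log_pu = -k * np.log(2.0) + np.sum(
        gammaln((d - j + 1) / 2.0) - ((d - j + 1) / 2.0) * np.log(np.pi)
    )

    log_lik = -N / 2.0 * np.sum(np.log(lam[:k])) - N * (d - k) / 2.0 * np.log(
        sigma2
    )

    # Hessian (Az) term over distinct eigenvalue pairs
    lam_hat = np.concatenate([lam[:k], np.full(d - k, sigma2)])
    log_az = 0.0
    for i in range(k):
        terms = (1.0 / lam_hat[i + 1 :] - 1.0 / lam_hat[i]) * (
            lam[i] - lam[i + 1 :]
        ) * N
        terms = np.maximum(terms, 1e-300)
        log_az += np.sum(np.log(terms))

    m = d * k - k * (k + 1) / 2.0
    return float(
        log_pu + log_lik - 0.5 * log_az + (m + k) / 2.0 * np.log(2.0 * np.pi)
        - k / 2.0 * np.log(N)
    )


def estimate_dimensionality(
    data: "AslSub | np.ndarray", mask: np.ndarray | None = None
) -> int:
    """Bayesian model order of the demeaned difference series.

    Accepts an :class:`~aslica.preprocess.AslSub` (uses its brain mask)
    or a T x V matrix.  Returns K clamped to [2, T-2].
    """
    Y = data.matrix(mask) if isinstance(data, AslSub) else np.asarray(data, float)
    T, V = Y.shape
    if T < 4:
        raise ValueError("need at least 4 volumes to estimate model order")
    Yd = Y - Y.mean(axis=0, keepdims=True)
    Yd -= Yd.mean(axis=1, keepdims=True)
    cov = (Yd @ Yd.T) / V
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.maximum(lam, 0.0)
    if np.sum(lam > 1e-12 * max(lam[0], 1e-30)) < 2:
        raise ValueError("degenerate data: rank < 2")

    # temporal demeaning removes one degree of freedom: the covariance has
    # an exact null eigenvalue along the constant vector; the evidence is
    # evaluated on the remaining T-1 dimensional spectrum
    lam = lam[: T - 1]
    d = lam.size
    # numerical rank bounds the admissible order (near-noiseless data has
    # an effectively degenerate tail that the PPCA noise floor cannot fit)
    rank = int(np.sum(lam > 1e-9 * lam[0]))
    k_max = max(min(T - 2, d - 1, rank - 1), 1)
    best_k, best_ev = 2, -np.inf
    for k in range(1, k_max + 1):
        ev = _laplace_evidence(lam, k, V)
        if ev > best_ev:
            best_ev, best_k = ev, k
    return int(np.clip(best_k, 2, T - 2))


# ---------------------------------------------------------------------------
# Symmetric fixed-point ICA
# ---------------------------------------------------------------------------


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(W @ W.T)
    s = np.maximum(s, 1e-12)
    return (u * (1.0 / np.sqrt(s))) @ u.T @ W


def _fastica_rotation(
    Z: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    """Symmetric fixed-point iteration, logcosh contrast.

    ``Z`` is K x V, whitened (unit covariance over V).  Returns the
    orthogonal unmixing matrix W (sources = W @ Z) and convergence flag.
    """
    K, V = Z.shape
    W = _sym_decorrelate(rng.standard_normal((K, K)))
    for _ in range(max_iter):
        S = W @ Z
        g = np.tanh(S)
        g_prime = (1.0 - g**2).mean(axis=1)
        W_new = (g @ Z.T) / V - g_prime[:, np.newaxis] * W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if delta < tol:
            return W, True
    return W, False


def _negentropy(S: np.ndarray) -> float:
    """Sum of logcosh negentropy approximations over sources (rows)."""
    # E[log cosh] of a standard normal
    gauss = 0.37456
    return float(np.sum((np.mean(np.log(np.cosh(S)), axis=1) - gauss) ** 2))


@dataclass
class IcaDecomposition:
    """Spatial maps + mixing matrix + bookkeeping of one decomposition."""

    maps: np.ndarray  # K x V, z-scored over V
    mixing: np.ndarray  # T x K, unit-variance columns
    amplitudes: np.ndarray  # K
    explained_variance_ratio: np.ndarray  # K
    eigenvalues: np.ndarray  # full covariance spectrum
    voxel_mean: np.ndarray  # 1 x V temporal mean field
    volume_mean: np.ndarray  # T x 1 spatial mean course
    mask: np.ndarray | None = None  # 3D in-brain mask (None for matrix input)

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def reconstruct(self) -> np.ndarray:
        """T x V reconstruction at the retained order (mean fields included)."""
        return (
            self.voxel_mean
            + self.volume_mean
            + self.mixing @ (self.amplitudes[:, np.newaxis] * self.maps)
        )


class SpatialICA:
    """Spatial ICA estimator (scikit-learn style).

    Parameters
    ----------
    n_components : fixed model order, or None for automatic estimation.
    n_restarts : fixed-point restarts; the run with the best contrast wins.
    random_state : seed fanned out to the restarts.
    var_norm : divide each voxel by its temporal standard deviation before
        decomposition (off by default: the subtracted series' amplitude
        structure is informative).
    max_iter, tol : fixed-point iteration controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    decomposition_ : :class:`IcaDecomposition`
    n_components_ : retained order
    converged_ : best restart converged within ``max_iter``
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_restarts: int = 5,
        random_state: int = 0,
        var_norm: bool = False,
        max_iter: int = 500,
        tol: float = 1e-7,
    ) -> None:
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.var_norm = var_norm
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "var_norm": self.var_norm,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "SpatialICA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, data: "AslSub | np.ndarray", mask: np.ndarray | None = None):
        """Decompose an :class:`AslSub` (over its brain mask) or a T x V matrix."""
        if isinstance(data, AslSub):
            if mask is None:
                mask = data.brain_mask
            Y = data.matrix(mask)
        else:
            Y = np.asarray(data, dtype=float)
        T, V = Y.shape

        if self.var_norm:
            sd = Y.std(axis=0, ddof=1, keepdims=True)
            Y = Y / np.where(sd > 1e-12, sd, 1.0)

        voxel_mean = Y.mean(axis=0, keepdims=True)
        Yd = Y - voxel_mean
        volume_mean = Yd.mean(axis=1, keepdims=True)
        Yd = Yd - volume_mean

        K = (
            self.n_components
            if self.n_components is not None
            else estimate_dimensionality(Yd)
        )
        U, s, Vt = np.linalg.svd(Yd, full_matrices=False)
        rank = int(np.sum(s > 1e-10 * max(s[0], 1e-30)))
        if K > rank:
            raise ValueError(f"requested {K} components but data rank is {rank}")

        # whitened spatial sources: unit variance, zero mean over voxels
        Z = np.sqrt(V) * Vt[:K]

        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best = None
        for ss in seeds:
            W, conv = _fastica_rotation(
                Z, np.random.default_rng(ss), self.max_iter, self.tol
            )
            score = _negentropy(W @ Z)
            if best is None or score > best[0]:
                best = (score, W, conv)
        if best is None or not best[2]:
            # bounded restarts exhausted without convergence: report, keep best
            import warnings

            warnings.warn(
                "fixed-point ICA did not fully converge within "
                f"{self.max_iter} iterations over {self.n_restarts} restarts",
                RuntimeWarning,
                stacklevel=2,
            )
        _, W, conv = best

        S = W @ Z  # K x V, unit variance rows
        # mixing so that mixing @ S equals the rank-K PCA reconstruction
        M = Yd @ S.T / V  # T x K

        # amplitude = column std (population); normalize both factors
        amp = M.std(axis=0, ddof=0)
        amp = np.where(amp > 1e-15, amp, 1.0)
        M = M / amp
        # order by descending explained variance, fix map sign by skewness
        order = np.argsort(amp)[::-1]
        M, S, amp = M[:, order], S[order], amp[order]
        skew = np.mean(S**3, axis=1)
        flip = np.where(skew < 0, -1.0, 1.0)
        S = S * flip[:, np.newaxis]
        M = M * flip[np.newaxis, :]

        total_var = float(np.sum(Yd**2)) / (T * V)
        evr = amp**2 / total_var if total_var > 0 else np.zeros_like(amp)

        self.decomposition_ = IcaDecomposition(
            maps=S,
            mixing=M,
            amplitudes=amp,
            explained_variance_ratio=evr,
            eigenvalues=(s**2) / V,
            voxel_mean=voxel_mean,
            volume_mean=volume_mean,
            mask=mask if isinstance(mask, np.ndarray) else None,
        )
        self.n_components_ = K
        self.converged_ = bool(conv)
        return self

    # -- persistence (MELODIC-style layout) --------------------------------

    def save(self, directory: str | Path, affine: np.ndarray | None = None,
             voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
        """Write ``melodic_IC.nii.gz`` / ``melodic_mix`` / ``melodic_FTmix``."""
        dec = self.decomposition_
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "melodic_mix", dec.mixing, fmt="%.10g")
        spectra = np.abs(np.fft.rfft(dec.mixing - dec.mixing.mean(axis=0), axis=0)) ** 2
        np.savetxt(directory / "melodic_FTmix", spectra[1:], fmt="%.10g")
        if dec.mask is not None:
            vols = np.zeros(dec.mask.shape + (dec.n_components,), dtype=np.float32)
            vols[dec.mask.astype(bool), :] = dec.maps.T
            aff = affine if affine is not None else np.eye(4)
            write_series(
                ImageSeries(vols, aff, voxel_sizes),
                directory / "melodic_IC.nii.gz",
            )
        return directory
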