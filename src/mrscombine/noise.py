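"""Inter-coil noise covariance estimation, correlated-noise generation, whitening.

Receive channels of a phased array pick up correlated thermal noise.  The
covariance is estimated from a signal-free spectral window (0.4-1.0 ppm by
default for in vivo 1H spectra) and used in two ways: to *whiten* the coil
dimension before SVD-based combination, and to *generate* realistic
correlated noise for simulation studies at scalable levels q = 1..7.

Conventions
-----------
The complex Gaussian draws have standard-normal real and imaginary parts
(total variance 2 per sample).  The generator's default follows the literal
form ``E_corr = L^H @ E_gaussian`` where ``psi = L L^H`` is the Cholesky
factorization; note this yields covariance proportional to ``L^H L``, which
differs from ``psi`` unless ``psi`` is diagonal.  Pass ``exact_cov=True`` to
use ``L`` instead, which reproduces ``psi`` exactly (up to the factor 2 from
the complex-Gaussian convention).  Pipelines that estimate the covariance
from the data they whiten are self-consistent under either form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import AcquisitionBlock, AcquisitionMeta, CoilMatrix, ppm_indices, to_frequency

__all__ = [
    "NoiseModel",
    "identity_noise_model",
    "extract_noise_region",
    "estimate_covariance",
    "estimate_block_noise",
    "generate_correlated_noise",
    "add_scaled_noise",
    "whiten",
    "unwhiten",
]

DEFAULT_NOISE_REGION = (0.4, 1.0)

_EIG_FLOOR_REL = 1e-10


@dataclass
class NoiseModel:
    """Estimated (or specified) inter-coil noise covariance with its factors.

    Attributes
    ----------
    psi : (C, C) complex ndarray
        Hermitian positive-semidefinite covariance estimate.
    cholesky : (C, C) complex ndarray
        Lower-triangular L with ``psi = L @ L.conj().T`` (eigen-floored
        reconstruction if psi is rank deficient).
    whitener : (C, C) complex ndarray
        ``W = D^{-1/2} G^H`` from the eigendecomposition ``psi = G D G^H``;
        satisfies ``W psi W^H = I`` when psi is full rank.
    n_samples_used : int
        Number of noise samples per coil behind the estimate (0 if specified
        analytically).
    rank_deficient : bool
        True when eigenvalues had to be floored to build the whitener.
    """

    psi: np.ndarray
    cholesky: np.ndarray
    whitener: np.ndarray
    n_samples_used: int = 0
    rank_deficient: bool = False

    @property
    def n_coils(self) -> int:
        return self.psi.shape[0]

    @property
    def whitener_inv(self) -> np.ndarray:
        """Inverse whitening transform ``W^{-1} = G D^{1/2}``."""
        return np.linalg.inv(self.whitener)

    @classmethod
    def from_psi(cls, psi: np.ndarray, n_samples_used: int = 0) -> "NoiseModel":
        """Build cholesky and whitening factors from a covariance matrix.

        The matrix is Hermitian-symmetrized first.  Eigenvalues below
        ``1e-10 * lambda_max`` are clamped to that floor (and the model
        flagged rank deficient) so that ``D^{-1/2}`` always exists.
        """
        psi = np.asarray(psi, dtype=np.complex128)
        if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
            raise ValueError(f"psi must be square, got shape {psi.shape}")
        psi = 0.5 * (psi + psi.conj().T)
        lam, G = np.linalg.eigh(psi)
        lam_max = lam[-1]
        if lam_max <= 0:
            raise ValueError("psi has no positive eigenvalue; cannot whiten")
        floor = _EIG_FLOOR_REL * lam_max
        deficient = bool(np.any(lam < floor))
        lam_f = np.maximum(lam, floor)
        whitener = (G / np.sqrt(lam_f)).conj().T  # D^{-1/2} G^H
        psi_f = (G * lam_f) @ G.conj().T
        psi_f = 0.5 * (psi_f + psi_f.conj().T)
        chol = np.linalg.cholesky(psi_f)
        return cls(
            psi=psi,
            cholesky=chol,
            whitener=whitener,
            n_samples_used=n_samples_used,
            rank_deficient=deficient,
        )


def identity_noise_model(n_coils: int) -> NoiseModel:
    """Noise model with uncorrelated unit-variance coils (psi = I)."""
    return NoiseModel.from_psi(np.eye(n_coils))


def extract_noise_region(
    data: AcquisitionBlock | CoilMatrix,
    meta: AcquisitionMeta | None = None,
    ppm_lo: float = DEFAULT_NOISE_REGION[0],
    ppm_hi: float = DEFAULT_NOISE_REGION[1],
) -> np.ndarray:
    """Frequency-domain samples of each coil in the noise-only ppm window.

    For a :class:`CoilMatrix` returns a (C, M) array; for a full
    :class:`AcquisitionBlock` a (C, A, M) array with one slice per average,
    so the covariance can be estimated independently per repeated sampling.
    A warning is issued when M < C (rank-deficient covariance ahead).
    """
    if isinstance(data, AcquisitionBlock):
        meta = data.meta
        arr = data.data
        domain = "time"
    else:
        if meta is None:
            raise ValueError("meta is required when passing a CoilMatrix")
        arr = data.data
        domain = data.domain_tag
    idx = ppm_indices(meta, ppm_lo, ppm_hi)
    spec = arr if domain == "frequency" else to_frequency(arr)
    out = spec[..., idx]
    if out.shape[-1] < arr.shape[0]:
        warnings.warn(
            f"noise region has {out.shape[-1]} samples for {arr.shape[0]} coils; "
            "covariance will be rank deficient",
            stacklevel=2,
        )
    return out


def estimate_covariance(e_hat: np.ndarray) -> NoiseModel:
    """Sample covariance ``psi = E E^H / M`` of noise-only measurements.

    Accepts a (C, M) matrix, or a (C, A, M) stack in which case the
    per-average covariances are averaged (each repeated sampling contributes
    an independent estimate).  The 1/M normalization keeps the scale
    independent of the width of the noise window.
    """
    e_hat = np.asarray(e_hat, dtype=np.complex128)
    if e_hat.ndim == 1:
        e_hat = e_hat[np.newaxis, :]
    if e_hat.ndim == 2:
        m = e_hat.shape[1]
        if m < 1:
            raise ValueError("need at least one noise sample per coil")
        psi = (e_hat @ e_hat.conj().T) / m
        n_used = m
    elif e_hat.ndim == 3:
        c, a, m = e_hat.shape
        if m < 1:
            raise ValueError("need at least one noise sample per coil")
        stacked = np.einsum("cam,dam->cd", e_hat, e_hat.conj()) / (a * m)
        psi = stacked
        n_used = a * m
    else:
        raise ValueError(f"expected 2-D or 3-D noise array, got ndim={e_hat.ndim}")
    return NoiseModel.from_psi(psi, n_samples_used=n_used)


def estimate_block_noise(
    block: AcquisitionBlock,
    ppm_lo: float = DEFAULT_NOISE_REGION[0],
    ppm_hi: float = DEFAULT_NOISE_REGION[1],
    pooled: bool = False,
) -> NoiseModel:
    """Estimate the noise model of an acquisition from its noise-only window.

    By default the covariance is estimated per average and averaged across
    averages; ``pooled=True`` concatenates all averages into one estimate.
    """
    e = extract_noise_region(block, ppm_lo=ppm_lo, ppm_hi=ppm_hi)
    if pooled:
        c = e.shape[0]
        e = e.reshape(c, -1)
    return estimate_covariance(e)


def generate_correlated_noise(
    model: NoiseModel,
    n_points: int,
    rng: np.random.Generator | int,
    exact_cov: bool = False,
) -> np.ndarray:
    """Draw one (C, n_points) realization of correlated complex noise.

    Real and imaginary parts of the underlying white draws are standard
    normal.  Default couples coils by ``L^H`` (the literal unit-level noise
    recipe); ``exact_cov=True`` couples by ``L`` so the population
    covariance equals ``2 * psi``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = model.n_coils
    white = rng.standard_normal((c, n_points)) + 1j * rng.standard_normal((c, n_points))
    factor = model.cholesky if exact_cov else model.cholesky.conj().T
    return factor @ white


def add_scaled_noise(
    block: AcquisitionBlock,
    model: NoiseModel,
    q: int,
    seed: int,
    exact_cov: bool = False,
) -> AcquisitionBlock:
    """Return ``X + q * E_corr`` with independent noise for every average.

    The per-average generator is seeded from the pair ``(seed, average)``,
    so the same seed reproduces the same noise field and the q-dependence is
    exactly affine: ``block(q) - block(0) = q * (block(1) - block(0))``.
    ``q=0`` returns an identical copy of the input.
    """
    if q < 0:
        raise ValueError(f"noise level q must be >= 0, got {q}")
    data = block.data.copy()
    if q > 0:
        for a in range(block.meta.n_averages):
            rng = np.random.default_rng([int(seed), a])
            data[:, a, :] += q * generate_correlated_noise(
                model, block.meta.n_points, rng, exact_cov=exact_cov
            )
    return AcquisitionBlock(data=data, meta=block.meta)


def whiten(x: CoilMatrix, model: NoiseModel) -> CoilMatrix:
    """Decorrelate the coil dimension: ``X_whitened = W X``."""
    if x.data.shape[0] != model.n_coils:
        raise ValueError(
            f"coil count mismatch: matrix has {x.data.shape[0]}, model {model.n_coils}"
        )
    return CoilMatrix(data=model.whitener @ x.data, domain_tag=x.domain_tag)


def unwhiten(x: CoilMatrix, model: NoiseModel) -> CoilMatrix:
    """Invert :func:`whiten` (W is always invertible after eigen-flooring)."""
    return CoilMatrix(data=model.whitener_inv @ x.data, domain_tag=x.domain_tag)
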