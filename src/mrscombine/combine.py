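"""Coil-combination algorithms: Brown, GLS, SVD/WSVD, and ASSVD.

All four methods estimate the ideal voxel spectrum ``m`` from the rank-1
acquisition model ``X = s m^T + E`` (coil sensitivities ``s``, correlated
noise ``E``).  The baseline methods (Brown, GLS, WSVD) consume the
across-average mean matrix; ASSVD alone consumes the full
coils x averages x points block, exploiting the stability of the coil
sensitivities between repeated samplings:

1. each average is pre-combined by WSVD;
2. a pointwise sensitivity estimate ``s_{c,a}(n)`` is formed by dividing the
   raw data by the (gauge-aligned) pre-combined signal;
3. the averages x points sensitivity plane of each coil is smoothed with a
   k x k uniform kernel;
4. each (average, point) coil vector is recombined by whitened least squares
   against the smoothed sensitivities, and the per-average solutions are
   averaged.

The pointwise, locally smoothed weights let the combination adapt to
sensitivity variation between samplings — the regime real repeatedly
sampled acquisitions live in.  When sensitivities are perfectly stable the
adaptivity is pure estimation cost; see docs/methods.md for the full
discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .datamodel import (
    AcquisitionBlock,
    AcquisitionMeta,
    CoilMatrix,
    CombinedSpectrum,
    from_frequency,
    ppm_indices,
    to_frequency,
)
from .noise import NoiseModel, whiten

__all__ = [
    "SensitivityField",
    "SvdSolution",
    "average_block",
    "combine_brown",
    "combine_gls",
    "pick_naa_sensitivity",
    "combine_svd",
    "combine_wsvd",
    "estimate_sensitivity_field",
    "smooth_sensitivity",
    "combine_assvd",
]

NAA_PPM = 2.0
SENSITIVITY_EPS_REL = 1e-9


@dataclass
class SensitivityField:
    """Pointwise per-coil sensitivities over the averages x points plane."""

    raw: np.ndarray  # (C, A, N) complex
    smoothed: np.ndarray  # (C, A, N) complex
    kernel_size: int

    def __post_init__(self) -> None:
        if self.raw.shape != self.smoothed.shape:
            raise ValueError("raw and smoothed sensitivity fields must share a shape")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd >= 1, got {self.kernel_size}")


@dataclass
class SvdSolution:
    """Rank-1 factorization of a coil matrix by its leading singular triplet."""

    combined: np.ndarray  # length N: sigma1 * conj(v1) * xi_m
    sensitivity: np.ndarray  # length C: u1 * xi_s
    sigma1: float
    xi: complex
    degenerate: bool = False  # top two singular values tied


def average_block(block: AcquisitionBlock) -> CoilMatrix:
    """Arithmetic mean over the averages dimension -> (C, N) time-domain matrix."""
    return CoilMatrix(data=block.data.mean(axis=1), domain_tag="time")


def _require_time_domain(x: CoilMatrix, op: str) -> np.ndarray:
    if x.domain_tag != "time":
        raise ValueError(f"{op} expects a time-domain coil matrix")
    return x.data


def combine_brown(x: CoilMatrix, conjugate_weights: bool = False) -> CombinedSpectrum:
    """Weight each coil by the first point of its time-domain signal and sum.

    The literal rule uses the first point itself as the weight; with
    ``conjugate_weights=True`` the conjugate is used instead, which cancels
    per-coil phase so the coils add constructively.
    """
    data = _require_time_domain(x, "combine_brown")
    w = data[:, 0].copy()
    if np.all(w == 0):
        raise ValueError("all first time-domain points are zero; Brown weights degenerate")
    if conjugate_weights:
        w = w.conj()
    fid = w @ data
    return CombinedSpectrum(
        fid=fid, method="brown", params={"conjugate_weights": conjugate_weights}
    )


def combine_gls(x: CoilMatrix, model: NoiseModel, s: np.ndarray) -> CombinedSpectrum:
    """Generalized least squares: ``m = ((s^H psi^-1 s)^-1 s^H psi^-1 X)^T``.

    The best linear unbiased estimate of ``m`` under the rank-1 model with
    noise covariance ``psi``; exact (unbiased) on noiseless rank-1 input.
    """
    s = np.asarray(s, dtype=np.complex128).ravel()
    if s.shape[0] != x.data.shape[0]:
        raise ValueError("sensitivity vector length must equal the coil count")
    if np.all(s == 0):
        raise ValueError("sensitivity vector is zero; GLS weights undefined")
    w = model.whitener
    sw = w @ s
    xw = w @ x.data
    fid = sw.conj() @ xw / np.vdot(sw, sw).real
    return CombinedSpectrum(fid=fid, method="gls", params={"domain": x.domain_tag})


def pick_naa_sensitivity(
    x: CoilMatrix,
    meta: AcquisitionMeta,
    center_ppm: float = NAA_PPM,
    half_width_ppm: float = 0.15,
) -> np.ndarray:
    """Per-coil complex spectrum value at the NAA peak (~2.0 ppm).

    For each coil, the value at the magnitude-maximizing bin of the summed
    magnitude spectrum within ``center_ppm +- half_width_ppm``; the shared
    bin keeps the relative coil phases meaningful.
    """
    idx = ppm_indices(meta, center_ppm - half_width_ppm, center_ppm + half_width_ppm)
    spec = x.data if x.domain_tag == "frequency" else to_frequency(x.data)
    window = spec[:, idx]
    peak_bin = int(np.argmax(np.abs(window).sum(axis=0)))
    return window[:, peak_bin]


def _gauge_phase(vec: np.ndarray) -> complex:
    """Unit phase factor making the reference element real and non-negative.

    The reference is the first element, or the largest-magnitude element if
    the first vanishes; a zero vector gets gauge 1.
    """
    ref = vec.flat[0]
    if ref == 0:
        k = int(np.argmax(np.abs(vec)))
        ref = vec.flat[k]
        if ref == 0:
            return 1.0 + 0j
    return abs(ref) / ref


def combine_svd(x: CoilMatrix) -> SvdSolution:
    """Rank-1 combination by the leading singular triplet of the coil matrix.

    ``combined = sigma1 * conj(v1) * xi`` and ``sensitivity = u1 / xi`` with
    the gauge ``xi`` (a unit complex scalar) fixed so the combined FID's
    first time-domain point is real and non-negative; the outer product
    ``sensitivity @ combined.T`` is exactly the best rank-1 Frobenius
    approximation of the input.  A tie between the top two singular values
    (within 1e-12 relative) is flagged; the factorization returned is the
    first triplet of a deterministic LAPACK ordering.
    """
    u, sig, vh = np.linalg.svd(x.data, full_matrices=False)
    degenerate = bool(len(sig) > 1 and sig[0] > 0 and (sig[0] - sig[1]) <= 1e-12 * sig[0])
    combined = sig[0] * vh[0]  # vh[0] is v1^H: rank-1 model X = s m^T has m ∝ conj(v1)
    xi = _gauge_phase(combined)
    return SvdSolution(
        combined=combined * xi,
        sensitivity=u[:, 0] / xi,
        sigma1=float(sig[0]),
        xi=xi,
        degenerate=degenerate,
    )


def combine_wsvd(x: CoilMatrix, model: NoiseModel) -> CombinedSpectrum:
    """Whitened SVD: whiten the coil dimension, then rank-1 SVD combination.

    The combined spectrum is the leading right-singular component of the
    whitened matrix; un-whitening applies to the sensitivity estimate
    (``W^-1 u1``), not to the length-N spectrum, whose gauge is free anyway.
    Equivalent to plain SVD (up to gauge) when psi is a multiple of the
    identity.
    """
    sol = combine_svd(whiten(x, model))
    return CombinedSpectrum(
        fid=sol.combined,
        method="wsvd",
        params={
            "sigma1": sol.sigma1,
            "degenerate": sol.degenerate,
            "sensitivity": model.whitener_inv @ sol.sensitivity,
        },
    )


def estimate_sensitivity_field(
    block: AcquisitionBlock,
    model: NoiseModel,
    domain: str = "time",
    eps_rel: float = SENSITIVITY_EPS_REL,
) -> SensitivityField:
    """Pointwise sensitivities from per-average WSVD pre-combination.

    For each average ``a`` the WSVD pre-combined signal ``m_a`` is computed
    and phase/scale-aligned (by the least-squares complex scalar) to the
    WSVD result of the across-average mean — per-average SVD gauges are
    independent, and an unaligned field would not be smooth across
    averages.  The sensitivity is then the clipped pointwise ratio::

        s_{c,a}(n) = x_{c,a}(n) * conj(m_a(n)) / max(|m_a(n)|^2, eps)

    with ``eps = eps_rel * max|m_a|^2`` guarding the zero crossings of
    ``m_a``.  The clip is exact (bias-free) wherever ``|m_a|`` is above the
    floor, so a noiseless constant-sensitivity block yields the constant
    field to machine precision.  ``domain`` selects whether the division
    happens on time-domain FIDs (default) or on spectra.
    """
    if domain not in ("time", "frequency"):
        raise ValueError(f"domain must be 'time' or 'frequency', got {domain!r}")
    c, a_count, n = block.data.shape
    data = block.data if domain == "time" else to_frequency(block.data)
    if not np.any(data):
        raise ValueError("block is identically zero; cannot estimate sensitivity")
    m_ref = combine_svd(
        CoilMatrix(data=model.whitener @ data.mean(axis=1), domain_tag=domain)
    ).combined
    raw = np.empty_like(data)
    for a in range(a_count):
        xa = data[:, a, :]
        if not np.any(xa):
            raise ValueError(f"average {a} is identically zero; cannot estimate sensitivity")
        sol = combine_svd(CoilMatrix(data=model.whitener @ xa, domain_tag=domain))
        m_a = sol.combined
        denom = np.vdot(m_a, m_a)
        z = np.vdot(m_a, m_ref) / denom if denom != 0 else 1.0
        m_a = m_a * z
        eps = eps_rel * float(np.max(np.abs(m_a)) ** 2)
        raw[:, a, :] = xa * m_a.conj() / np.maximum(np.abs(m_a) ** 2, eps)
    return SensitivityField(raw=raw, smoothed=raw.copy(), kernel_size=1)


def smooth_sensitivity(field: SensitivityField, k: int) -> SensitivityField:
    """Smooth each coil's averages x points plane with a k x k uniform kernel.

    Replicate padding at the borders preserves constant fields; ``k=1`` is
    the identity.  ``k`` must be odd and no larger than either plane
    dimension.
    """
    c, a, n = field.raw.shape
    if k % 2 == 0 or k < 1 or k > min(a, n):
        raise ValueError(f"kernel size must be odd and within [1, {min(a, n)}], got {k}")
    if k == 1:
        return SensitivityField(raw=field.raw, smoothed=field.raw.copy(), kernel_size=1)
    sm = np.empty_like(field.raw)
    for ci in range(c):
        plane = field.raw[ci]
        sm[ci] = uniform_filter(plane.real, size=k, mode="nearest") + 1j * uniform_filter(
            plane.imag, size=k, mode="nearest"
        )
    return SensitivityField(raw=field.raw, smoothed=sm, kernel_size=k)


def combine_assvd(
    block: AcquisitionBlock,
    model: NoiseModel,
    k: int = 7,
    domain: str = "time",
    eps_rel: float = SENSITIVITY_EPS_REL,
) -> CombinedSpectrum:
    """Average-smoothing SVD combination of a repeatedly sampled acquisition.

    Runs the full pipeline (per-average WSVD, sensitivity estimation,
    k x k smoothing, per-point whitened least squares) and returns the mean
    of the per-average solutions.  The default kernel size 7 is the value
    found optimal on repeatedly sampled in vivo brain spectra.  Points where
    the smoothed sensitivity vanishes across all coils are combined with
    uniform unit weights and counted in ``params['uniform_weight_points']``.
    """
    field = smooth_sensitivity(
        estimate_sensitivity_field(block, model, domain=domain, eps_rel=eps_rel), k
    )
    data = block.data if domain == "time" else to_frequency(block.data)
    w = model.whitener
    xw = np.einsum("dc,can->dan", w, data)
    sw = np.einsum("dc,can->dan", w, field.smoothed)
    num = np.einsum("can,can->an", sw.conj(), xw)
    den = np.einsum("can,can->an", sw.conj(), sw).real
    # vanishing smoothed sensitivity (relative to the plane) leaves the
    # per-point solve unconstrained; fall back to uniform unit weights there
    zero = den <= 1e-12 * den.max() if den.max() > 0 else den == 0
    n_zero = int(zero.sum())
    if n_zero:
        num = np.where(zero, xw.mean(axis=0), num)
        den = np.where(zero, 1.0, den)
    m_per_average = num / den
    fid = m_per_average.mean(axis=0)
    if domain == "frequency":
        fid = from_frequency(fid)
    fid = fid * _gauge_phase(fid)
    return CombinedSpectrum(
        fid=fid,
        method="assvd",
        params={"kernel_size": k, "domain": domain, "uniform_weight_points": n_zero},
    )
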