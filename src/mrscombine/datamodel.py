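"""Core data containers, spectral-axis conventions, and HDF5 round-tripping.

A single-voxel MRS acquisition is a complex array of free induction decays
(FIDs) indexed ``[coil, average, point]``.  Every algorithm in this package
consumes either the full three-dimensional block or a two-dimensional
coil x points matrix derived from it.

Axis convention
---------------
The spectrum is displayed with chemical shift (ppm) decreasing from left to
right, the standard orientation in NMR/MRS.  ``to_frequency`` therefore
returns DFT bins reordered so that index 0 is the most downfield (highest
ppm) bin, and :func:`ppm_axis` is strictly monotone decreasing.  The ppm
value of frequency offset ``f`` (Hz, relative to the carrier) is
``reference_ppm + f / transmitter_frequency_mhz``.  The water reference
defaults to 4.7 ppm, the standard in vivo value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Literal

import h5py
import numpy as np

__all__ = [
    "AcquisitionMeta",
    "AcquisitionBlock",
    "CoilMatrix",
    "CombinedSpectrum",
    "FormatError",
    "ppm_axis",
    "ppm_indices",
    "to_frequency",
    "from_frequency",
    "read_block",
    "write_block",
    "write_spectrum",
    "read_spectrum",
    "export_spectrum_csv",
]

WATER_PPM = 4.7


class FormatError(ValueError):
    """Raised when an on-disk container is missing fields or inconsistent."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry and spectral calibration.

    Parameters
    ----------
    spectral_bandwidth : float
        Sampling bandwidth in Hz (a typical 3 T protocol uses 2000 Hz).
    n_points : int
        Number of complex points per FID.
    n_coils : int
        Number of receive channels.
    n_averages : int
        Number of repeated samplings of the voxel.
    transmitter_frequency : float
        Carrier frequency in MHz (~128 MHz for protons at 3 T).
    reference_ppm : float
        Chemical shift assigned to the carrier (spectral center).
    """

    spectral_bandwidth: float
    n_points: int
    n_coils: int
    n_averages: int
    transmitter_frequency: float = 128.0
    reference_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        if self.spectral_bandwidth <= 0:
            raise ValueError("spectral_bandwidth must be positive")
        if self.transmitter_frequency <= 0:
            raise ValueError("transmitter_frequency must be positive")
        for name in ("n_points", "n_coils", "n_averages"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_bandwidth

    @property
    def hz_per_ppm(self) -> float:
        return self.transmitter_frequency  # MHz carrier -> Hz per ppm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_coils, self.n_averages, self.n_points)


@dataclass
class AcquisitionBlock:
    """Raw multichannel, multi-average time-domain acquisition (C, A, N)."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.shape != self.meta.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match metadata {self.meta.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("acquisition data contains non-finite entries")


@dataclass
class CoilMatrix:
    """A coils x points matrix: one average, or the across-average mean."""

    data: np.ndarray
    domain_tag: Literal["time", "frequency"] = "time"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("CoilMatrix requires a 2-D array (coils x points)")


@dataclass
class CombinedSpectrum:
    """Result of a coil-combination method, stored as a time-domain FID."""

    fid: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fid = np.asarray(self.fid, dtype=np.complex128).ravel()


def _freqs_descending(meta: AcquisitionMeta) -> np.ndarray:
    """DFT frequency offsets (Hz) ordered to match the display convention."""
    f = np.fft.fftshift(np.fft.fftfreq(meta.n_points, d=meta.dwell_time))
    return f[::-1]


def ppm_axis(meta: AcquisitionMeta) -> np.ndarray:
    """Chemical-shift axis (ppm), monotone decreasing, length ``n_points``.

    Index 0 is the most downfield bin; the reference ppm sits within one
    bin of the axis midpoint.  This mapping is the single source of truth
    for every ppm-region selection in the package.
    """
    return meta.reference_ppm + _freqs_descending(meta) / meta.hz_per_ppm


def ppm_indices(meta: AcquisitionMeta, ppm_lo: float, ppm_hi: float) -> np.ndarray:
    """Indices of bins whose centers fall in the half-open interval [lo, hi).

    Returned in ascending index order (i.e. descending ppm).  Raises if the
    interval selects no bins.
    """
    if ppm_lo >= ppm_hi:
        raise ValueError(f"empty ppm interval [{ppm_lo}, {ppm_hi})")
    axis = ppm_axis(meta)
    idx = np.nonzero((axis >= ppm_lo) & (axis < ppm_hi))[0]
    if idx.size == 0:
        raise ValueError(
            f"ppm interval [{ppm_lo}, {ppm_hi}) lies outside the axis "
            f"[{axis.min():.3f}, {axis.max():.3f}]"
        )
    return idx


def to_frequency(fid: np.ndarray) -> np.ndarray:
    """DFT along the last axis, reordered to the descending-ppm convention."""
    fid = np.asarray(fid)
    spec = np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1)
    return spec[..., ::-1]


def from_frequency(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_frequency`; round-trips to ~1e-15 relative error."""
    spectrum = np.asarray(spectrum)
    return np.fft.ifft(np.fft.ifftshift(spectrum[..., ::-1], axes=-1), axis=-1)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_META_ATTRS = {
    "spectral_bandwidth_hz": "spectral_bandwidth",
    "transmitter_frequency_mhz": "transmitter_frequency",
    "reference_ppm": "reference_ppm",
    "n_coils": "n_coils",
    "n_averages": "n_averages",
    "n_points": "n_points",
}


def write_block(block: AcquisitionBlock, path) -> None:
    """Write an acquisition to an HDF5 file (dataset ``fid`` + root attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fid", data=block.data)
        for attr, fld in _META_ATTRS.items():
            f.attrs[attr] = getattr(block.meta, fld)


def read_block(path) -> AcquisitionBlock:
    """Read an acquisition written by :func:`write_block`.

    Raises :class:`FormatError` naming any missing dataset/attribute, or on a
    shape/metadata mismatch.
    """
    with h5py.File(path, "r") as f:
        if "fid" not in f:
            raise FormatError(f"{path}: missing dataset 'fid'")
        kwargs = {}
        for attr, fld in _META_ATTRS.items():
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
            val = f.attrs[attr]
            kwargs[fld] = int(val) if fld.startswith("n_") else float(val)
        meta = AcquisitionMeta(**kwargs)
        data = f["fid"][...]
    if data.shape != meta.shape:
        raise FormatError(
            f"{path}: dataset shape {data.shape} inconsistent with metadata {meta.shape}"
        )
    return AcquisitionBlock(data=data, meta=meta)


def write_spectrum(spec: CombinedSpectrum, path) -> None:
    """Write a combined spectrum (dataset ``fid`` + method provenance attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fid", data=spec.fid)
        f.attrs["method"] = spec.method
        for key, val in spec.params.items():
            if isinstance(val, (str, int, float, bool, np.integer, np.floating)):
                f.attrs[key] = val


def read_spectrum(path) -> CombinedSpectrum:
    with h5py.File(path, "r") as f:
        if "fid" not in f:
            raise FormatError(f"{path}: missing dataset 'fid'")
        if "method" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'method'")
        fid = f["fid"][...]
        method = str(f.attrs["method"])
        params = {k: f.attrs[k] for k in f.attrs if k != "method"}
    return CombinedSpectrum(fid=fid, method=method, params=params)


def export_spectrum_csv(spec: CombinedSpectrum, meta: AcquisitionMeta, path) -> None:
    """Export a combined spectrum as CSV with columns ppm, real, imag, magnitude."""
    axis = ppm_axis(meta)
    s = to_frequency(spec.fid)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ppm", "real", "imag", "magnitude"])
        for p, v in zip(axis, s):
            w.writerow([f"{p:.6f}", repr(v.real), repr(v.imag), repr(abs(v))])
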