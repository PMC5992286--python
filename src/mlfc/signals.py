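"""Filterbank decomposition, analytic signal, and ROI-representative series.

All filtering is zero-phase (forward-backward) 3rd-order Butterworth, the
standard choice for narrowband decomposition of electrophysiological data:
it preserves instantaneous phase relationships that the connectivity
estimators downstream depend on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

from .bands import BandSpec

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import VoxelCluster

#: Seconds dropped from each end of an epoch after the Hilbert transform,
#: absorbing filtfilt/Hilbert edge transients before connectivity.
EDGE_TRIM_S = 0.5


def _band_sos(band: BandSpec, fs: float) -> np.ndarray:
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is at or above the "
            f"Nyquist frequency {fs / 2} Hz (fs={fs} Hz)"
        )
    return sps.butter(3, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass along the last axis.

    Output has the same length as the input (forward-backward filtering).
    """
    x = np.asarray(x, dtype=float)
    sos = _band_sos(band, fs)
    return sps.sosfiltfilt(sos, x, axis=-1)


@dataclass(frozen=True)
class AnalyticBandSignal:
    """Instantaneous phase and envelope of a narrowband signal."""

    phase: np.ndarray  # radians, wrapped to (-pi, pi]
    envelope: np.ndarray  # non-negative amplitude
    band: BandSpec | None = None


def analytic(x: np.ndarray, band: BandSpec | None = None) -> AnalyticBandSignal:
    """Analytic-signal phase and envelope via the Hilbert transform.

    The caller is responsible for ``x`` being narrowband; the instantaneous
    phase of a broadband signal is not physically interpretable.

    Raises
    ------
    ValueError
        If the input is (near-)constant, for which phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    scale = np.abs(x).max(initial=0.0)
    if np.std(x, axis=-1).min() <= 1e-12 * (scale + 1.0):
        raise ValueError("analytic signal undefined for a constant input")
    z = sps.hilbert(x, axis=-1)
    return AnalyticBandSignal(phase=np.angle(z), envelope=np.abs(z), band=band)


def trim_edges(a: np.ndarray, fs: float, trim_s: float = EDGE_TRIM_S) -> np.ndarray:
    """Drop ``trim_s`` seconds from each end of the last axis."""
    k = int(round(trim_s * fs))
    if k == 0:
        return a
    if 2 * k >= a.shape[-1]:
        raise ValueError(
            f"cannot trim {trim_s} s ({2 * k} samples) from a length-"
            f"{a.shape[-1]} epoch"
        )
    return a[..., k:-k]


def roi_pca(cluster: "VoxelCluster") -> np.ndarray:
    """First principal-component score series of a voxel cluster.

    Computed on the mean-centred voxels x time matrix (epochs concatenated),
    giving one representative series per ROI. The sign is aligned so the
    component correlates positively with the mean voxel series, which makes
    the result independent of the eigensolver's sign convention.
    """
    V = np.asarray(cluster.voxel_series, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("roi_pca needs a voxels x time matrix with >= 2 voxels")
    Vc = V - V.mean(axis=1, keepdims=True)
    if not np.any(Vc):
        raise ValueError("all-zero voxel cluster has no principal component")
    # time-courses are long; eigendecompose the small voxels x voxels Gram matrix
    C = Vc @ Vc.T
    w, U = np.linalg.eigh(C)
    u = U[:, -1]
    score = u @ Vc
    ref = Vc.mean(axis=0)
    if np.dot(score, ref) < 0:
        score = -score
    return score


def roi_centroid(cluster: "VoxelCluster") -> np.ndarray:
    """Series of the voxel closest to the cluster's coordinate centroid.

    The centroid is the unweighted mean of voxel coordinates; ties are
    broken by the lowest voxel index. The series is returned unmodified.
    """
    coords = np.asarray(cluster.voxel_coords, dtype=float)
    centroid = coords.mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    return np.asarray(cluster.voxel_series, dtype=float)[int(np.argmin(d))]
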