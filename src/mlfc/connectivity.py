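"""Intra- and cross-frequency functional connectivity estimators.

Phase coupling is quantified by the phase-locking value

    PLV  = (1/T) | sum_t exp(i (phi_X(t) - phi_Y(t))) |

and by its imaginary part

    iPLV = (1/T) | Im sum_t exp(i (phi_X(t) - phi_Y(t))) |

which discards zero-lag contributions and is therefore resistant to
instantaneous field spread (volume conduction). Amplitude coupling is the
absolute Pearson correlation of Hilbert envelopes (non-orthogonalized).

Cross-frequency coupling comes in two flavours:

* phase-amplitude coupling (PAC): the HF envelope of one signal is
  band-pass filtered in the LF range, Hilbert-transformed, and its phase
  is phase-locked against the LF phase of the other signal;
* cross-frequency envelope correlation: envelopes extracted in two
  different bands are correlated.

All estimators are computed within each epoch and averaged across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .bands import DEFAULT_BANDS, BandSpec, CouplingMode, coupling_modes
from .signals import EDGE_TRIM_S, analytic, bandpass, trim_edges
from .simulate import EpochedRecording

Estimator = Literal["plv", "iplv", "corr_env"]
ESTIMATORS = ("plv", "iplv", "corr_env")


# --------------------------------------------------------------------------
# scalar estimators
# --------------------------------------------------------------------------


def _as_epochs(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[None, :]
    if a.ndim == 2:
        return a
    raise ValueError("expected a 1-D series or an epochs x samples array")


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y = _as_epochs(x), _as_epochs(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return x, y


def plv(phx: np.ndarray, phy: np.ndarray) -> float:
    """Phase-locking value of two phase series, averaged across epochs."""
    phx, phy = _check_pair(phx, phy)
    return float(np.mean(np.abs(np.mean(np.exp(1j * (phx - phy)), axis=-1))))


def iplv(phx: np.ndarray, phy: np.ndarray) -> float:
    """Imaginary part of the phase-locking value (zero-lag insensitive)."""
    phx, phy = _check_pair(phx, phy)
    return float(np.mean(np.abs(np.imag(np.mean(np.exp(1j * (phx - phy)), axis=-1)))))


def corr_env(ax: np.ndarray, ay: np.ndarray) -> float:
    """Absolute Pearson correlation of two envelope series, per epoch,
    averaged across epochs."""
    ax, ay = _check_pair(ax, ay)
    axc = ax - ax.mean(axis=-1, keepdims=True)
    ayc = ay - ay.mean(axis=-1, keepdims=True)
    sx = np.sqrt((axc**2).sum(axis=-1))
    sy = np.sqrt((ayc**2).sum(axis=-1))
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("zero-variance envelope: correlation undefined")
    r = (axc * ayc).sum(axis=-1) / (sx * sy)
    return float(np.mean(np.abs(r)))


def _phase_sync(phx: np.ndarray, phy: np.ndarray, index: Estimator) -> float:
    return plv(phx, phy) if index == "plv" else iplv(phx, phy)


#: Minimum coefficient of variation of an HF envelope below which the
#: modulation phase is considered undefined (constant-amplitude carrier).
_ENVELOPE_CV_FLOOR = 0.05


def _check_envelope_cv(a_hf: np.ndarray) -> None:
    cv = np.std(a_hf, axis=-1) / np.mean(a_hf, axis=-1)
    if np.min(cv) < _ENVELOPE_CV_FLOOR:
        raise ValueError(
            "degenerate HF envelope (near-constant amplitude): "
            "modulation phase undefined"
        )


def pac_iplv(
    x: np.ndarray,
    y: np.ndarray,
    lf: BandSpec,
    hf: BandSpec,
    fs: float,
    index: Estimator = "iplv",
    trim_s: float = EDGE_TRIM_S,
) -> float:
    """Phase-amplitude coupling of x's LF phase with y's HF envelope.

    Pipeline: band-pass x in ``lf`` -> phi_LF; band-pass y in ``hf`` ->
    envelope A_HF; band-pass A_HF within ``lf`` -> Hilbert -> phi'; return
    the phase-locking (``index``: plv or iplv) of (phi_LF, phi'). Epoch
    edges are trimmed after the final Hilbert transform. Directional:
    symmetric graph entries take the max over the two assignments.
    """
    if lf.hi > hf.lo:
        raise ValueError(f"LF band {lf} overlaps HF band {hf}")
    x, y = _check_pair(x, y)
    phi_lf = analytic(bandpass(x, lf, fs), lf).phase
    a_hf = analytic(bandpass(y, hf, fs), hf).envelope
    _check_envelope_cv(a_hf)
    phi_mod = analytic(bandpass(a_hf, lf, fs), lf).phase
    phi_lf = trim_edges(phi_lf, fs, trim_s)
    phi_mod = trim_edges(phi_mod, fs, trim_s)
    return _phase_sync(phi_mod, phi_lf, index)


def cfc_corr_env(
    x: np.ndarray,
    y: np.ndarray,
    band_a: BandSpec,
    band_b: BandSpec,
    fs: float,
    trim_s: float = EDGE_TRIM_S,
) -> float:
    """Cross-frequency envelope correlation: envelope of x in ``band_a``
    against envelope of y in ``band_b`` (absolute Pearson, epoch-averaged)."""
    if band_a.lo >= band_b.lo:
        raise ValueError("band_a must precede band_b")
    x, y = _check_pair(x, y)
    a = trim_edges(analytic(bandpass(x, band_a, fs), band_a).envelope, fs, trim_s)
    b = trim_edges(analytic(bandpass(y, band_b, fs), band_b).envelope, fs, trim_s)
    return corr_env(a, b)


# --------------------------------------------------------------------------
# graph assembly
# --------------------------------------------------------------------------


@dataclass
class SLFCG:
    """A single-layer functional connectivity graph: one N x N symmetric
    non-negative weight matrix for one estimator and one coupling mode."""

    estimator: str
    mode: CouplingMode
    W: np.ndarray
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.isfinite(W).all():
            raise ValueError("W contains non-finite entries")
        if (W < 0).any():
            raise ValueError("W must be non-negative")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.W = W

    @property
    def n_rois(self) -> int:
        return self.W.shape[0]


def _pairwise_phase(Z: np.ndarray, index: Estimator) -> np.ndarray:
    """Epoch-averaged pairwise phase locking from unit phasors
    Z (epochs x channels x T); returns a channels x channels matrix."""
    E, C, T = Z.shape
    out = np.zeros((C, C))
    for e in range(E):
        M = Z[e] @ Z[e].conj().T / T
        out += np.abs(M) if index == "plv" else np.abs(M.imag)
    return out / E


def _pairwise_cross_phase(Zx: np.ndarray, Zy: np.ndarray, index: Estimator) -> np.ndarray:
    """Directional epoch-averaged phase locking between two phasor stacks:
    entry (i, j) locks Zx channel i against Zy channel j."""
    E, C, T = Zx.shape
    out = np.zeros((C, Zy.shape[1]))
    for e in range(E):
        M = Zx[e] @ Zy[e].conj().T / T
        out += np.abs(M) if index == "plv" else np.abs(M.imag)
    return out / E


def _standardize_rows(A: np.ndarray, context: str) -> np.ndarray:
    Ac = A - A.mean(axis=-1, keepdims=True)
    s = Ac.std(axis=-1, keepdims=True)
    if np.any(s == 0):
        bad = np.argwhere(s[..., 0] == 0)
        raise ValueError(f"zero-variance envelope in {context} at (epoch, channel) {bad[0]}")
    return Ac / s


def _pairwise_corr(Aa: np.ndarray, Ab: np.ndarray, context: str) -> np.ndarray:
    """Epoch-averaged |Pearson r| between envelope stacks (epochs x C x T)."""
    E, C, T = Aa.shape
    out = np.zeros((C, Ab.shape[1]))
    Aa = _standardize_rows(Aa, context)
    Ab = _standardize_rows(Ab, context)
    for e in range(E):
        out += np.abs(Aa[e] @ Ab[e].T / T)
    return out / E


def _symmetrize(D: np.ndarray, how: str) -> np.ndarray:
    if how == "max":
        W = np.maximum(D, D.T)
    elif how == "mean":
        W = 0.5 * (D + D.T)
    else:
        raise ValueError(f"unknown symmetrization {how!r}")
    np.fill_diagonal(W, 0.0)
    return W


def build_sl_fcgs(
    rec: EpochedRecording,
    estimator: Estimator,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    trim_s: float = EDGE_TRIM_S,
    cfc_symmetrize: str = "max",
    roi_labels: Sequence[str] | None = None,
) -> list[SLFCG]:
    """Estimate all single-layer graphs for one subject.

    Returns graphs in the fixed mode order of :func:`mlfc.bands.coupling_modes`
    (intra per band, then cross pairs): 7 + 21 = 28 with the default
    filterbank. For phase estimators the cross-frequency graphs carry
    PAC; for ``corr_env`` they carry cross-frequency envelope correlation.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    bands = tuple(bands)
    fs = rec.fs

    # per-band analytic decomposition of every channel/epoch
    phasors: dict[str, np.ndarray] = {}  # trimmed unit phasors e^{i phi}
    env_full: dict[str, np.ndarray] = {}  # untrimmed envelopes (PAC input)
    env_trim: dict[str, np.ndarray] = {}
    for band in bands:
        xb = bandpass(rec.data, band, fs)
        ab = analytic(xb, band)
        phasors[band.name] = np.exp(1j * trim_edges(ab.phase, fs, trim_s))
        env_full[band.name] = ab.envelope
        env_trim[band.name] = trim_edges(ab.envelope, fs, trim_s)

    graphs: list[SLFCG] = []
    for mode in coupling_modes(bands):
        try:
            if mode.kind == "intra":
                b = mode.bands[0]
                if estimator == "corr_env":
                    W = _pairwise_corr(env_trim[b.name], env_trim[b.name], mode.label)
                else:
                    W = _pairwise_phase(phasors[b.name], estimator)
                np.fill_diagonal(W, 0.0)
                W = 0.5 * (W + W.T)  # exact symmetry against float round-off
            else:
                lf, hf = mode.bands
                if estimator == "corr_env":
                    D = _pairwise_corr(env_trim[lf.name], env_trim[hf.name], mode.label)
                else:
                    # phase of the LF-filtered HF envelope, per channel
                    try:
                        phi_mod = analytic(bandpass(env_full[hf.name], lf, fs), lf).phase
                    except ValueError as err:
                        raise ValueError(f"degenerate HF envelope: {err}") from err
                    z_mod = np.exp(1j * trim_edges(phi_mod, fs, trim_s))
                    # entry (i, j): phase of i's LF rhythm vs j's modulated envelope
                    D = _pairwise_cross_phase(phasors[lf.name], z_mod, estimator)
                W = _symmetrize(D, cfc_symmetrize)
        except ValueError as err:
            raise ValueError(f"estimator {estimator!r} failed for mode {mode.label}: {err}") from err
        graphs.append(SLFCG(estimator=estimator, mode=mode, W=W, roi_labels=roi_labels))
    return graphs
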