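"""Synthetic two-group cohorts with known, planted coupling structure.

Every downstream stage of the pipeline (connectivity estimation, graph
filtering, classification) is validated against cohorts generated here,
because the planted coupling parameters are the ground truth that real
recordings never provide.

The generative model per region-of-interest (ROI) channel is::

    x_roi(t) = pink_noise(t) + sqrt(snr) * sum of planted components

where each planted component realises one coupling mode on one ROI pair:

* ``intra``  - two signals in the same band with a constant phase lag;
  the locked component carries a slow independent amplitude envelope, so
  pure phase coupling does not masquerade as envelope correlation.
* ``pac``    - phase-amplitude coupling: the phase of a low-frequency (LF)
  narrowband noise modulates the envelope of a high-frequency (HF)
  carrier as ``(1 + m cos(phi_LF - lag)) * carrier``.
* ``env``    - two narrowband signals (possibly different bands) sharing a
  slow multiplicative envelope with mixing weight rho.

Carriers are stochastic narrowband processes rather than sinusoids:
independent realizations use band-passed white noise, while planted
components ride smooth frequency-modulated carriers confined to the band
interior, so re-filtering on the analysis side recovers the planted
phases and envelopes instead of filter-distorted versions of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandSpec, CouplingMode
from .signals import analytic, bandpass

#: Between-subject sd of planted coupling strengths (truncated normal).
SUBJECT_JITTER_SD = 0.05


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedEdge:
    """One planted coupling on a ROI pair.

    ``strength`` is the coupling parameter of the matching generator
    (mixing weight for intra, modulation depth for pac, envelope sharing
    for env), in [0, 1]. ``phase_lag`` is the constant phase lag (intra)
    or the modulation lag (pac), in radians; unused for env.
    """

    roi_i: int
    roi_j: int
    mode: CouplingMode
    strength: float
    phase_lag: float = math.pi / 2

    def __post_init__(self) -> None:
        if self.roi_i == self.roi_j:
            raise ValueError(f"self-edge ({self.roi_i},{self.roi_j}) not allowed")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"strength {self.strength} outside [0, 1]")


@dataclass(frozen=True)
class CouplingPlan:
    """Full specification of a synthetic cohort's coupling structure."""

    n_rois: int
    edges: Sequence[PlannedEdge]
    #: (edge index, strength shift applied to group 2) pairs
    group_effects: Sequence[tuple[int, float]] = ()
    bands: Sequence[BandSpec] = DEFAULT_BANDS
    noise_exponent: float = 1.0  # 1/f^a background slope
    snr: float = 3.0  # planted-component to background power ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        for e in self.edges:
            if not (0 <= e.roi_i < self.n_rois and 0 <= e.roi_j < self.n_rois):
                raise ValueError(f"edge ({e.roi_i},{e.roi_j}) outside 0..{self.n_rois - 1}")
        for idx, _ in self.group_effects:
            if not 0 <= idx < len(self.edges):
                raise ValueError(f"group effect refers to missing edge {idx}")


@dataclass
class EpochedRecording:
    """Per-subject epoched multichannel time series."""

    subject_id: str
    group: int  # 1 or 2
    data: np.ndarray  # epochs x channels x samples
    fs: float
    epoch_len_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be epochs x channels x samples, epochs >= 1")
        if self.data.shape[2] != int(round(self.fs * self.epoch_len_s)):
            raise ValueError(
                f"samples {self.data.shape[2]} != fs*epoch_len_s "
                f"({self.fs}*{self.epoch_len_s})"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")
        if self.group not in (1, 2):
            raise ValueError("group must be 1 or 2")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class VoxelCluster:
    """A ROI's voxel-level series, coordinates, and the true source."""

    roi_id: int
    voxel_series: np.ndarray  # voxels x samples
    voxel_coords: np.ndarray  # voxels x 3, mm
    true_source: np.ndarray  # samples

    def __post_init__(self) -> None:
        self.voxel_series = np.asarray(self.voxel_series, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=float)
        if self.voxel_series.shape[0] < 2:
            raise ValueError("voxel cluster needs >= 2 voxels")
        if not np.isfinite(self.voxel_coords).all():
            raise ValueError("voxel coordinates must be finite")


# --------------------------------------------------------------------------
# elementary generators
# --------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    s = x.std()
    return x / s if s > 0 else x


def pink_noise(n: int, exponent: float = 1.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    rng = np.random.default_rng() if rng is None else rng
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    return _standardize(np.fft.irfft(spec * gain, n))


def _narrowband(rng: np.random.Generator, band: BandSpec, fs: float, n: int) -> np.ndarray:
    """Unit-variance narrowband noise: band-passed white noise."""
    return _standardize(bandpass(rng.standard_normal(n), band, fs))


def _slow_envelope(
    rng: np.random.Generator, fs: float, n: int, cutoff: float
) -> np.ndarray:
    """Positive, slowly varying amplitude envelope (low-passed noise)."""
    from scipy import signal as sps

    sos = sps.butter(3, cutoff, btype="lowpass", fs=fs, output="sos")
    z = _standardize(sps.sosfiltfilt(sos, rng.standard_normal(n)))
    return np.clip(1.0 + 0.4 * z, 0.05, None)


def _check_band(band: BandSpec, fs: float) -> None:
    if not (0 < band.lo < band.hi < fs / 2):
        raise ValueError(
            f"band {band.name!r} ({band.lo}-{band.hi} Hz) violates the Nyquist "
            f"constraint 0 < lo < hi < fs/2 = {fs / 2} Hz"
        )


def _fm_phase(rng: np.random.Generator, band: BandSpec, fs: float, n: int) -> np.ndarray:
    """Phase of a smooth frequency-modulated carrier confined to the band.

    The instantaneous frequency drifts slowly around the band centre and
    never reaches the band edges, so zero-phase re-filtering in the same
    band recovers the phase essentially unchanged.
    """
    from scipy import signal as sps

    f0, hw = (band.lo + band.hi) / 2, (band.hi - band.lo) / 2
    cutoff = min(0.5, band.lo / 2)
    sos = sps.butter(3, cutoff, btype="lowpass", fs=fs, output="sos")
    z = _standardize(sps.sosfiltfilt(sos, rng.standard_normal(n)))
    f = f0 + 0.6 * hw * np.tanh(z)
    return 2 * np.pi * np.cumsum(f) / fs + rng.uniform(0, 2 * np.pi)


def generate_coupled_pair(
    band: BandSpec,
    phase_lag: float,
    strength: float,
    fs: float,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband signals with a planted constant phase lag.

    Both signals ride on the same smooth in-band FM carrier phase but
    carry independent slow amplitude envelopes, so phase coupling does
    not leak into envelope correlation. The second signal mixes the
    lag-shifted locked component at weight ``strength`` with an
    independent narrowband realization at weight ``1 - strength``.

    At strength=1 the instantaneous phase difference is constant; at
    strength=0 the signals are independent.
    """
    _check_band(band, fs)
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi = _fm_phase(rng, band, fs, n)
    env_cut = min(1.0, band.lo / 2)
    x = _standardize(_slow_envelope(rng, fs, n, env_cut) * np.cos(phi))
    locked = _standardize(_slow_envelope(rng, fs, n, env_cut) * np.cos(phi + phase_lag))
    indep = _narrowband(rng, band, fs, n)
    y = strength * locked + (1.0 - strength) * indep
    return x, _standardize(y) if strength < 1 else y


def generate_pac_pair(
    lf: BandSpec,
    hf: BandSpec,
    depth: float,
    mod_lag: float,
    fs: float,
    n: int,
    seed: int | np.random.Generator,
    noise_floor: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """A LF signal and a HF signal whose envelope it modulates.

    The HF series is ``(1 + depth * cos(phi_LF(t) - mod_lag)) * carrier``
    with a unit-envelope narrowband carrier, plus an unmodulated
    narrowband HF noise floor (weight ``noise_floor``) so that the
    detectability of the coupling grows with ``depth``. depth=0 gives an
    HF amplitude independent of the LF phase; ``noise_floor=0`` plants
    the stated envelope exactly.
    """
    _check_band(lf, fs)
    _check_band(hf, fs)
    if lf.hi > hf.lo:
        raise ValueError(f"LF band {lf} overlaps HF band {hf}; need lf.hi <= hf.lo")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("modulation depth must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = _narrowband(rng, lf, fs, n)
    phi_lf = analytic(x, lf).phase
    # smooth in-band carrier: unit envelope, no spectral leakage outside hf
    carrier = np.cos(_fm_phase(rng, hf, fs, n))
    y = (1.0 + depth * np.cos(phi_lf - mod_lag)) * carrier
    if noise_floor:
        y = y + noise_floor * _narrowband(rng, hf, fs, n)
    return x, y


def generate_env_pair(
    band_a: BandSpec,
    band_b: BandSpec,
    rho: float,
    fs: float,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two band-limited signals sharing a slow multiplicative envelope.

    Each signal's envelope mixes an own and a shared slow fluctuation
    with weights sqrt(1-rho) and sqrt(rho), so the correlation between
    the two planted envelopes equals rho: coincident at rho=1,
    independent at rho=0.
    """
    _check_band(band_a, fs)
    _check_band(band_b, fs)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cutoff = min(1.0, band_a.lo / 2, band_b.lo / 2)
    e_shared = _slow_envelope(rng, fs, n, cutoff)
    e_a = _slow_envelope(rng, fs, n, cutoff)
    e_b = _slow_envelope(rng, fs, n, cutoff)
    # smooth in-band carriers: their unit envelope survives re-filtering,
    # so the planted slow envelope is what the estimator recovers
    ca = np.cos(_fm_phase(rng, band_a, fs, n))
    cb = np.cos(_fm_phase(rng, band_b, fs, n))
    wo, ws = math.sqrt(1.0 - rho), math.sqrt(rho)
    x = np.clip(1.0 + wo * (e_a - 1.0) + ws * (e_shared - 1.0), 0.05, None) * ca
    y = np.clip(1.0 + wo * (e_b - 1.0) + ws * (e_shared - 1.0), 0.05, None) * cb
    return x, y


def generate_roi_voxels(
    true_source: np.ndarray,
    n_voxels: int,
    snr: float,
    spread_mm: float,
    seed: int | np.random.Generator,
    roi_id: int = 0,
) -> VoxelCluster:
    """A synthetic voxel cluster around one true source series.

    Each voxel carries the (standardized) true source scaled by a gain
    decaying with distance from the cluster centroid, plus independent
    noise at the stated linear snr. Voxel 0 sits exactly at the centroid.
    """
    if n_voxels < 2:
        raise ValueError("need n_voxels >= 2")
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s = _standardize(np.asarray(true_source, dtype=float))
    others = rng.normal(scale=spread_mm, size=(n_voxels - 1, 3))
    # voxel 0 at the mean of the others == the centroid of the full cluster
    coords = np.vstack([others.mean(axis=0), others])
    d = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    gains = np.exp(-d / spread_mm)
    noise_sd = 0.0 if np.isinf(snr) else 1.0 / math.sqrt(snr)
    series = gains[:, None] * s + noise_sd * rng.standard_normal((n_voxels, s.size))
    return VoxelCluster(roi_id=roi_id, voxel_series=series, voxel_coords=coords, true_source=s)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def _edge_component(
    edge: PlannedEdge,
    strength: float,
    fs: float,
    n: int,
    rng: np.random.Generator,
    lf_cache: dict | None = None,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Realize one planted edge; returns (modulator series or None if the
    modulator rhythm was already emitted for this subject, target series).

    PAC edges sharing a modulator ROI reuse one LF rhythm per (ROI, band):
    a region has a single slow oscillation that can drive several targets.
    """
    mode = edge.mode
    if mode.kind == "intra":
        return generate_coupled_pair(mode.bands[0], edge.phase_lag, strength, fs, n, rng)
    lf, hf = mode.bands
    if _is_pac(mode):
        key = (edge.roi_i, lf.name)
        if lf_cache is not None and key in lf_cache:
            x, phi_lf = lf_cache[key]
            carrier = np.cos(_fm_phase(rng, hf, fs, n))
            y = (1.0 + strength * np.cos(phi_lf - edge.phase_lag)) * carrier
            y = y + 0.4 * _narrowband(rng, hf, fs, n)
            return None, y
        x, y = generate_pac_pair(lf, hf, strength, edge.phase_lag, fs, n, rng)
        if lf_cache is not None:
            lf_cache[key] = (x, analytic(x, lf).phase)
        return x, y
    return generate_env_pair(lf, hf, strength, fs, n, rng)


def _is_pac(mode: CouplingMode) -> bool:
    # non-overlapping ordered band pairs admit PAC; the planner marks the
    # intent through the edge's estimator-facing kind tag
    return getattr(mode, "_pac", True)


def pac_mode(lf: BandSpec, hf: BandSpec) -> CouplingMode:
    """Cross-frequency mode realized as phase-amplitude coupling."""
    m = CouplingMode("cross", (lf, hf))
    object.__setattr__(m, "_pac", True)
    return m


def env_mode(band_a: BandSpec, band_b: BandSpec) -> CouplingMode:
    """Cross-frequency mode realized as shared-envelope coupling."""
    m = CouplingMode("cross", (band_a, band_b))
    object.__setattr__(m, "_pac", False)
    return m


def generate_cohort(
    plan: CouplingPlan,
    n_subjects_per_group: int,
    epochs: int = 20,
    epoch_len_s: float = 4.0,
    fs: float = 250.0,
) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Generate a two-group cohort of epoched recordings plus ground truth.

    Planted strengths are jittered per subject (truncated normal,
    sd 0.05) and shifted by the plan's group effects for group 2.
    Reproducible: the same plan seed yields bit-identical cohorts.
    """
    if n_subjects_per_group < 2:
        raise ValueError("need >= 2 subjects per group for cross-validation")
    samples = int(round(fs * epoch_len_s))
    total = epochs * samples
    deltas = dict(plan.group_effects)
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(2 * n_subjects_per_group)

    recordings: list[EpochedRecording] = []
    k = 0
    for group in (1, 2):
        for s_idx in range(n_subjects_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            chans = np.empty((plan.n_rois, total))
            for c in range(plan.n_rois):
                chans[c] = pink_noise(total, plan.noise_exponent, rng)
            amp = math.sqrt(plan.snr)
            lf_cache: dict = {}
            for e_idx, edge in enumerate(plan.edges):
                strength = edge.strength + (deltas.get(e_idx, 0.0) if group == 2 else 0.0)
                strength = float(np.clip(strength + rng.normal(0.0, SUBJECT_JITTER_SD), 0.0, 1.0))
                sx, sy = _edge_component(edge, strength, fs, total, rng, lf_cache)
                if sx is not None:
                    chans[edge.roi_i] += amp * _standardize(sx)
                chans[edge.roi_j] += amp * _standardize(sy)
            data = chans.reshape(plan.n_rois, epochs, samples).transpose(1, 0, 2)
            recordings.append(
                EpochedRecording(
                    subject_id=f"g{group}_s{s_idx:02d}",
                    group=group,
                    data=data,
                    fs=fs,
                    epoch_len_s=epoch_len_s,
                )
            )

    truth = pd.DataFrame(
        {
            "roi_i": [e.roi_i for e in plan.edges],
            "roi_j": [e.roi_j for e in plan.edges],
            "kind": [e.mode.kind for e in plan.edges],
            "mode": [e.mode.label for e in plan.edges],
            "pac": [e.mode.kind == "cross" and _is_pac(e.mode) for e in plan.edges],
            "strength": [e.strength for e in plan.edges],
            "phase_lag": [e.phase_lag for e in plan.edges],
            "delta_group2": [deltas.get(i, 0.0) for i in range(len(plan.edges))],
        }
    )
    return recordings, truth


def default_plan(n_rois: int = 20, seed: int = 0) -> CouplingPlan:
    """Desk-scale default: 10 group-differential alpha1 edges (delta=0.5)
    plus a PAC (delta->gamma1) and a shared-envelope (alpha1:alpha2) edge."""
    if n_rois * (n_rois - 1) // 2 < 12:
        raise ValueError(f"default plan needs >= 12 distinct ROI pairs; n_rois={n_rois} is too small")
    b = {s.name: s for s in DEFAULT_BANDS}
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    while len(pairs) < 12:
        i, j = sorted(rng.choice(n_rois, size=2, replace=False))
        if (i, j) not in pairs:
            pairs.append((int(i), int(j)))
    edges = [
        PlannedEdge(i, j, CouplingMode("intra", (b["alpha1"],)), 0.2, math.pi / 3)
        for i, j in pairs[:10]
    ]
    edges.append(PlannedEdge(*pairs[10], pac_mode(b["delta"], b["gamma1"]), 0.8))
    edges.append(PlannedEdge(*pairs[11], env_mode(b["alpha1"], b["alpha2"]), 0.8))
    group_effects = [(i, 0.5) for i in range(10)]
    return CouplingPlan(n_rois=n_rois, edges=edges, group_effects=group_effects, seed=seed)
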