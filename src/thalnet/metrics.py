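"""Functional-connectivity and spectral evaluation metrics.

Phase-locking value (PLV) in a narrow band is the FC estimator: signals are
zero-phase band-pass filtered, instantaneous phases come from the analytic
signal, and PLV_ij is the modulus of the time-averaged phase-difference
phasor. Dynamical FC (dFC) applies the same estimator on sliding windows
and correlates the windowed FC patterns; two dFC matrices are compared by
the two-sample Kolmogorov-Smirnov distance between their correlation-value
distributions. Spectral summaries (Welch PSD peak, band areas), a
signal-to-noise ratio and a cortex/driver relative-power ratio round out
the panel used by the parameter explorations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import ks_2samp, pearsonr

ALPHA_BAND = (8.0, 12.0)

__all__ = [
    "ALPHA_BAND",
    "FCMatrix",
    "DFCMatrix",
    "bandpass_filter",
    "instantaneous_phase",
    "plv_matrix",
    "fc_similarity",
    "dfc_matrix",
    "n_windows",
    "ks_distance",
    "spectral_summary",
    "snr",
    "relative_power",
]


@dataclass
class FCMatrix:
    """PLV functional-connectivity matrix with its band tag."""

    values: np.ndarray
    band: tuple = ALPHA_BAND
    region_labels: list | None = None
    region_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("FC diagonal must be 1")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("PLV entries must lie in [0, 1]")


@dataclass
class DFCMatrix:
    """Window-by-window correlation matrix of sliding-window FC patterns."""

    values: np.ndarray
    window_length: float  # s
    overlap: float        # fraction
    band: tuple = ALPHA_BAND

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dFC matrix must be square")

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle correlation sample."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def bandpass_filter(signals, low: float, high: float, fs: float, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward, no net phase shift)."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if high >= fs / 2:
        raise ValueError("band edge exceeds Nyquist frequency")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, signals, axis=-1)


def instantaneous_phase(filtered_signals, fs: float | None = None, edge_s: float = 1.0):
    """Analytic-signal phase in (-pi, pi] per sample.

    Returns ``(phases, edge_samples)`` where ``edge_samples`` marks the
    region (``edge_s`` seconds at each end when ``fs`` is given) to exclude
    from phase statistics because of filter/Hilbert edge effects.
    """
    x = np.atleast_2d(np.asarray(filtered_signals, dtype=float))
    if np.allclose(x, 0.0) or np.ptp(x, axis=-1).min() == 0:
        raise ValueError("no oscillation: constant or all-zero signal")
    phases = np.angle(sps.hilbert(x, axis=-1))
    edge = int(round(edge_s * fs)) if fs else 0
    # short records keep at least half their samples after trimming
    edge = min(edge, x.shape[-1] // 4)
    return phases, edge


def plv_matrix(phases, exclude_edges: int = 0,
               band=ALPHA_BAND, region_labels=None) -> FCMatrix:
    """Pairwise phase-locking value: |<exp(i (phi_i - phi_j))>_t|."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[0] < 2:
        raise ValueError("need at least two signals")
    if exclude_edges:
        phases = phases[:, exclude_edges:-exclude_edges]
    if phases.shape[1] < 2:
        raise ValueError("too few samples after edge exclusion")
    z = np.exp(1j * phases)
    # PLV_ij = |mean_t z_i conj(z_j)|
    plv = np.abs(z @ z.conj().T) / phases.shape[1]
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return FCMatrix(plv, band=band, region_labels=region_labels)


def fc_similarity(fc_sim, fc_ref, region_mask=None) -> float:
    """Pearson r between upper triangles of two FC matrices.

    ``region_mask`` (boolean or index array) restricts both matrices to the
    same region subset — conventionally the cortical regions — before
    vectorizing the strictly upper triangle.
    """
    a = fc_sim.values if isinstance(fc_sim, FCMatrix) else np.asarray(fc_sim, float)
    b = fc_ref.values if isinstance(fc_ref, FCMatrix) else np.asarray(fc_ref, float)
    if region_mask is not None:
        idx = np.asarray(region_mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        a = a[np.ix_(idx, idx)]
        b = b[np.ix_(idx, idx)]
    if a.shape != b.shape:
        raise ValueError("FC matrices differ in shape after masking")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant FC vector: correlation undefined")
    return float(pearsonr(x, y)[0])


def n_windows(n_samples: int, window: int, step: int) -> int:
    """Closed-form sliding-window count: floor((T - w)/step) + 1."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def dfc_matrix(signals, fs: float, window_s: float = 4.0, overlap: float = 0.5,
               band=ALPHA_BAND, region_mask=None) -> DFCMatrix:
    """Sliding-window PLV dynamical-FC matrix.

    Filters once over the whole record, extracts phases, computes PLV per
    window of ``window_s`` seconds with fractional ``overlap``, and returns
    the matrix of Pearson correlations between the upper-triangle FC
    patterns of every window pair.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    w = int(round(window_s * fs))
    step = max(int(round(w * (1.0 - overlap))), 1)
    nw = n_windows(signals.shape[1], w, step)
    if nw < 2:
        raise ValueError("fewer than two dFC windows")
    filtered = bandpass_filter(signals, band[0], band[1], fs)
    phases, _ = instantaneous_phase(filtered, fs)
    if region_mask is not None:
        idx = np.asarray(region_mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        phases = phases[idx]
    iu = np.triu_indices(phases.shape[0], k=1)
    patterns = np.empty((nw, iu[0].size))
    for k in range(nw):
        seg = phases[:, k * step: k * step + w]
        patterns[k] = plv_matrix(seg, band=band).values[iu]
    dfc = np.corrcoef(patterns)
    np.fill_diagonal(dfc, 1.0)
    return DFCMatrix(dfc, window_length=window_s, overlap=overlap, band=band)


def ks_distance(dfc_a, dfc_b) -> float:
    """Two-sample KS statistic between dFC correlation distributions.

    Accepts :class:`DFCMatrix` objects or plain samples of correlation
    values; matrices contribute their off-diagonal upper triangles.
    """
    a = dfc_a.upper_values() if isinstance(dfc_a, DFCMatrix) else np.asarray(dfc_a, float).ravel()
    b = dfc_b.upper_values() if isinstance(dfc_b, DFCMatrix) else np.asarray(dfc_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty dFC sample")
    return float(ks_2samp(a, b).statistic)


def spectral_summary(signals, fs: float, bands: dict | None = None,
                     nperseg_s: float = 4.0) -> dict:
    """Welch PSD panel: per-node spectra, averaged-spectrum peak, band areas.

    Returns a dict with ``freqs``, ``psd`` (n_nodes x n_freqs), ``peak_hz``
    (argmax of the node-averaged spectrum), ``total_power`` per node, and
    ``band_power`` per requested band (trapezoid-integrated).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    nperseg = min(int(round(nperseg_s * fs)), signals.shape[1])
    if signals.shape[1] < 8:
        raise ValueError("signal shorter than one Welch segment")
    freqs, psd = sps.welch(signals, fs=fs, nperseg=nperseg, axis=-1)
    mean_psd = psd.mean(axis=0)
    peak_hz = float(freqs[np.argmax(mean_psd)])
    out = {
        "freqs": freqs,
        "psd": psd,
        "peak_hz": peak_hz,
        "total_power": np.trapezoid(psd, freqs, axis=-1),
    }
    if bands:
        out["band_power"] = {
            name: np.trapezoid(psd[:, (freqs >= lo) & (freqs <= hi)],
                               freqs[(freqs >= lo) & (freqs <= hi)], axis=-1)
            for name, (lo, hi) in bands.items()
        }
    return out


def snr(signals, eta: float, node_set=None) -> float:
    """Signal-to-noise ratio: mean half peak-to-peak amplitude / noise std.

    ``signals`` are post-transient outputs; amplitude per node is
    (max - min) / 2 and the average over ``node_set`` (default: all nodes)
    is divided by the Gaussian input noise std ``eta``.
    """
    if not eta > 0:
        raise ValueError("SNR undefined for eta = 0")
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if node_set is not None:
        x = x[np.asarray(node_set)]
    amp = np.ptp(x, axis=-1) / 2.0
    return float(amp.mean() / eta)


def relative_power(spectra: dict, cortical_set, driver_set) -> float:
    """Mean total spectral area over cortical nodes / over driver nodes."""
    cortical_set = np.asarray(cortical_set)
    driver_set = np.asarray(driver_set)
    if cortical_set.size == 0 or driver_set.size == 0:
        raise ValueError("empty node set")
    total = np.asarray(spectra["total_power"], dtype=float)
    return float(total[cortical_set].mean() / total[driver_set].mean())
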