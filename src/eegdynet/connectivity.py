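"""Pairwise functional-connectivity estimators between EEG channels.

Four estimators, all returning weights in [0, 1]:

* **MSC** — magnitude squared coherence, ``|S_xy|^2 / (S_xx S_yy)``, averaged
  over the in-band frequency bins.  Sensitive to any linear dependence,
  including zero-lag volume conduction.
* **iCOH** — band-average of ``|Im K_xy(f)|`` where ``K_xy`` is the coherency.
  Zero for instantaneously mixed signals, hence robust to volume conduction.
* **PLI** — phase lag index: the absolute mean sign of the instantaneous
  phase difference (Hilbert phases), likewise blind to zero-lag coupling.
* **CORR** — absolute Pearson correlation.

Spectra are Welch averaged periodograms (1 s Hann segments, 50% overlap by
default) — short segments are the only well-conditioned choice inside 3 s
sliding windows.  PLI expects already band-limited inputs; the band
restriction comes from the upstream band-pass, not from the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window, hilbert

from .io import BandSpec, EEGRecording

__all__ = [
    "SpectralParams",
    "ConnectivityMatrix",
    "CONNECTIVITY_METHODS",
    "msc",
    "icoh",
    "pli",
    "pearson_abs",
    "connectivity_matrix",
]

CONNECTIVITY_METHODS = ("MSC", "ICOH", "PLI", "CORR")

#: fraction of the analytic signal trimmed at each end before PLI averaging
#: (Hilbert-transform boundary distortion is severe inside short windows)
PLI_EDGE_TRIM = 0.10


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimation parameters for the coherence-family estimators."""

    segment_len: float = 1.0
    overlap_frac: float = 0.5
    taper: str = "hann"

    def nperseg(self, fs: float) -> int:
        n = int(round(self.segment_len * fs))
        if n < 32:
            raise ValueError(
                f"segment_len x fs = {n} samples; need >= 32 for a usable spectrum"
            )
        return n

    def __post_init__(self):
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must lie in [0, 1)")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel weight matrix for one method and band."""

    weights: np.ndarray
    method: str
    band: BandSpec
    channel_labels: list

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if len(self.channel_labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.channel_labels,
                            columns=self.channel_labels)

    def to_edgelist(self) -> pd.DataFrame:
        """Long format: one row per unordered channel pair."""
        rows = []
        n = self.n_channels
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"node_i": self.channel_labels[i],
                             "node_j": self.channel_labels[j],
                             "weight": self.weights[i, j]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectral machinery
# ---------------------------------------------------------------------------

def _welch_cross_spectra(data: np.ndarray, fs: float, sp: SpectralParams):
    """Averaged-periodogram auto/cross spectra for all channel pairs.

    Returns ``(freqs, S)`` with ``S[i, j, f] = mean_seg conj(F_i) F_j``.
    Constant detrending per segment, as is standard for Welch estimates.
    """
    n_ch, n = data.shape
    nperseg = sp.nperseg(fs)
    if n < nperseg:
        raise ValueError(
            f"signal of {n} samples shorter than one {nperseg}-sample segment"
        )
    step = max(1, int(round(nperseg * (1 - sp.overlap_frac))))
    starts = np.arange(0, n - nperseg + 1, step)
    win = get_window(sp.taper, nperseg)
    segs = np.stack([data[:, s:s + nperseg] for s in starts], axis=1)
    segs = segs - segs.mean(axis=2, keepdims=True)
    F = np.fft.rfft(segs * win, axis=2)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    S = np.einsum("isf,jsf->ijf", np.conj(F), F) / len(starts)
    return freqs, S


def _band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    mask = (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)
    if not mask.any():
        raise ValueError(
            f"no frequency bins inside band {band.name} [{band.low}, {band.high}] Hz; "
            "increase segment_len"
        )
    return mask


def _coherency(data: np.ndarray, fs: float, sp: SpectralParams):
    freqs, S = _welch_cross_spectra(data, fs, sp)
    auto = np.real(np.einsum("iif->if", S))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    return freqs, K


def _check_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"signal lengths differ: {x.size} vs {y.size}")
    return x, y


def msc(x, y, fs: float, band: BandSpec, sp: SpectralParams = SpectralParams()) -> float:
    """Band-averaged magnitude squared coherence of one signal pair."""
    x, y = _check_pair(x, y)
    freqs, K = _coherency(np.vstack([x, y]), fs, sp)
    mask = _band_bins(freqs, band)
    return float(np.mean(np.abs(K[0, 1, mask]) ** 2))


def icoh(x, y, fs: float, band: BandSpec, sp: SpectralParams = SpectralParams()) -> float:
    """Band-averaged absolute imaginary coherency of one signal pair."""
    x, y = _check_pair(x, y)
    freqs, K = _coherency(np.vstack([x, y]), fs, sp)
    mask = _band_bins(freqs, band)
    return float(np.mean(np.abs(np.imag(K[0, 1, mask]))))


def _instantaneous_phases(data: np.ndarray) -> np.ndarray:
    ph = np.angle(hilbert(data, axis=1))
    n = data.shape[1]
    trim = int(round(PLI_EDGE_TRIM * n))
    if n - 2 * trim < 2:
        trim = 0
    return ph[:, trim:n - trim] if trim else ph


def pli(x, y) -> float:
    """Phase lag index of two already band-limited signals.

    ``| mean_t sign(phi_x(t) - phi_y(t)) |`` with the phase difference wrapped
    to (-pi, pi].  The first and last 10% of the analytic signal are discarded
    before averaging.
    """
    x, y = _check_pair(x, y)
    ph = _instantaneous_phases(np.vstack([x, y]))
    d = ph[0] - ph[1]
    wrapped = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return float(abs(np.mean(np.sign(wrapped))))


def pearson_abs(x, y) -> float:
    """Absolute Pearson product-moment correlation."""
    x, y = _check_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(abs(r), 1.0))


# ---------------------------------------------------------------------------
# full matrices
# ---------------------------------------------------------------------------

def connectivity_matrix(rec: EEGRecording, method: str, band: BandSpec,
                        sp: SpectralParams = SpectralParams()) -> ConnectivityMatrix:
    """All-pairs connectivity of one record with the selected estimator."""
    m = method.upper()
    if m == "COHERENCE":
        m = "MSC"
    if m not in CONNECTIVITY_METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: "
            + ", ".join(CONNECTIVITY_METHODS)
        )
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    data = rec.data
    n = rec.n_channels

    if m in ("MSC", "ICOH"):
        freqs, K = _coherency(data, rec.fs, sp)
        mask = _band_bins(freqs, band)
        if m == "MSC":
            W = np.mean(np.abs(K[:, :, mask]) ** 2, axis=2)
        else:
            W = np.mean(np.abs(np.imag(K[:, :, mask])), axis=2)
            W = 0.5 * (W + W.T)  # |Im| is symmetric; enforce exactly
    elif m == "PLI":
        ph = _instantaneous_phases(data)
        W = np.empty((n, n))
        for i in range(n):
            d = ph[i][None, :] - ph
            wrapped = np.mod(d + np.pi, 2 * np.pi) - np.pi
            W[i] = np.abs(np.mean(np.sign(wrapped), axis=1))
        W = 0.5 * (W + W.T)
    else:  # CORR
        sd = data.std(axis=1)
        if np.any(sd == 0):
            bad = [rec.channel_labels[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance channels: {', '.join(bad)}")
        W = np.abs(np.corrcoef(data))
        W = np.clip(0.5 * (W + W.T), 0.0, 1.0)

    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(weights=W, method=m, band=band,
                              channel_labels=list(rec.channel_labels))
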