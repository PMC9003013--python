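"""Reading, preprocessing, band decomposition and segmentation of multichannel EEG.

The in-memory container is :class:`EEGRecording`: a channels x samples array in
microvolts with a sampling rate and ordered channel labels.  Records can be read
from EDF (via mne) or from plain delimited text matrices (header row = channel
labels, one row per channel).  Preprocessing follows common clinical-EEG
practice: anti-aliased downsampling and zero-phase FIR band-pass filtering, so
that no inter-channel phase shifts are introduced (phase-based connectivity
depends on this).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "BandSpec",
    "TEN_TWENTY_LABELS",
    "read_recording",
    "write_recording",
    "resample",
    "bandpass",
    "standard_bands",
    "split_segments",
]

#: The 19 scalp electrodes of the international 10-20 montage.
TEN_TWENTY_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]


@dataclass
class EEGRecording:
    """A labeled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    subject_id : str
        Identifier of the participant the record came from.
    group : str or None
        Optional group label (e.g. ``"PC"`` / ``"PE"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high")
        if self.high > fs / 2:
            raise ValueError(
                f"band {self.name}: high edge {self.high} Hz exceeds Nyquist {fs / 2} Hz"
            )


def standard_bands() -> list[BandSpec]:
    """The six analysis bands: Delta, Theta, Alpha-1, Alpha-2, Beta and full band."""
    return [
        BandSpec("Delta", 0.5, 4.0),
        BandSpec("Theta", 4.0, 8.0),
        BandSpec("Alpha-1", 8.0, 10.0),
        BandSpec("Alpha-2", 10.0, 12.0),
        BandSpec("Beta", 12.0, 30.0),
        BandSpec("Full", 0.5, 45.0),
    ]


def band_by_name(name: str) -> BandSpec:
    for b in standard_bands():
        if b.name.lower() == name.lower():
            return b
    raise ValueError(
        f"unknown band {name!r}; choose from "
        + ", ".join(b.name for b in standard_bands())
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_recording(path, fs_hint: float | None = None) -> EEGRecording:
    """Read an EDF file or a delimited text matrix.

    Delimited matrices carry no sampling rate, so ``fs_hint`` is required for
    them.  The header row holds the channel labels; each subsequent row is one
    channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_delimited(path, fs_hint)


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    try:
        data = raw.get_data(units="uV")
    except (ValueError, TypeError):  # channels without a dimension
        data = raw.get_data() * 1e6
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def _read_delimited(path: Path, fs_hint: float | None) -> EEGRecording:
    if fs_hint is None:
        raise ValueError(
            "delimited matrices carry no sampling rate: pass fs_hint (Hz)"
        )
    with open(path) as fh:
        header = fh.readline().strip()
    delim = "," if "," in header else "\t" if "\t" in header else None
    labels = [t.strip() for t in header.split(delim) if t.strip()]
    data = np.loadtxt(path, skiprows=1, delimiter=delim, ndmin=2)
    if data.shape[0] != len(labels):
        raise ValueError(
            f"header lists {len(labels)} channels but matrix has {data.shape[0]} rows"
        )
    return EEGRecording(data=data, fs=float(fs_hint), channel_labels=labels,
                        subject_id=path.stem)


def write_recording(rec: EEGRecording, path) -> Path:
    """Write a recording to ``path``: ``.edf`` -> 16-bit EDF, else delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        delim = "," if path.suffix.lower() == ".csv" else "\t"
        with open(path, "w") as fh:
            fh.write(delim.join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.data, fmt="%.6f", delimiter=delim)
    return path


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal plain-EDF writer (16-bit, one 1-s data record per second).

    A trailing part-second that does not fill a whole data record is dropped;
    EDF requires complete records.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("record shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * spr]
    n_sig = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.rint((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(rec.subject_id or "X", 80)
    header += _edf_field("eegdynet export", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_sig + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_sig, 4)

    def sig_fields(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += sig_fields(rec.channel_labels, 16)
    header += sig_fields([""] * n_sig, 80)
    header += sig_fields(["uV"] * n_sig, 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmin], 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmax], 8)
    header += sig_fields([dmin] * n_sig, 8)
    header += sig_fields([dmax] * n_sig, 8)
    header += sig_fields([""] * n_sig, 80)
    header += sig_fields([spr] * n_sig, 8)
    header += sig_fields([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = dig[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def edf_quantization_step(rec: EEGRecording) -> float:
    """Worst-case amplitude resolution of a 16-bit EDF export of ``rec``."""
    rng = np.ptp(rec.data, axis=1)
    rng = np.where(rng <= 0, 1.0, rng)
    return float(rng.max() / 65535)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased downsampling to ``target_fs`` (polyphase)."""
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling requested ({rec.fs} -> {target_fs} Hz); only "
            "downsampling is supported"
        )
    if abs(target_fs - rec.fs) < 1e-12:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, fs=float(target_fs))


def design_bandpass_fir(low: float, high: float, fs: float,
                        max_taps: int | None = None) -> np.ndarray:
    """Hamming-windowed linear-phase band-pass FIR.

    The transition bandwidth is 25% of the lower edge, a common EEG choice
    that keeps the Delta band's 0.5 Hz edge steep without absurd filter
    lengths at higher bands.
    """
    trans = 0.25 * low
    numtaps = int(math.ceil(3.3 * fs / trans))
    if max_taps is not None:
        numtaps = min(numtaps, max_taps)
    numtaps |= 1  # odd -> Type I linear phase
    return sps.firwin(numtaps, [low, high], pass_zero=False,
                      window="hamming", fs=fs)


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering via FFT convolution with reflected padding."""
    n = data.shape[1]
    pad = min(len(taps), n - 1)
    left = data[:, 1 : pad + 1][:, ::-1]
    right = data[:, -pad - 1 : -1][:, ::-1]
    ext = np.concatenate([left, data, right], axis=1)
    once = sps.fftconvolve(ext, taps[None, :], mode="same", axes=1)
    twice = sps.fftconvolve(once[:, ::-1], taps[None, :], mode="same", axes=1)[:, ::-1]
    return twice[:, pad : pad + n]


def bandpass(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase band-pass filter (forward-backward FIR).

    Zero phase means no group delay and no inter-channel phase distortion,
    which the phase-based connectivity estimators (PLI, iCOH) require.
    """
    band.validate(rec.fs)
    # cap the filter at a third of the record so the reflection padding fits
    taps = design_bandpass_fir(band.low, band.high, rec.fs,
                               max_taps=max(33, rec.n_samples // 3))
    out = _zero_phase_filter(rec.data, taps)
    return replace(rec, data=out)


def split_segments(rec: EEGRecording, min_len: float) -> list[EEGRecording]:
    """Cut a record into consecutive non-overlapping segments of >= ``min_len`` s.

    ``floor(duration / min_len)`` segments are produced; a trailing remainder
    shorter than ``min_len`` is appended to the final segment so no data is
    discarded.  Records shorter than ``min_len`` pass through whole with a
    warning.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    n_seg = int(rec.duration // min_len)
    if n_seg == 0:
        warnings.warn(
            f"record {rec.subject_id!r} is {rec.duration:.1f} s, shorter than the "
            f"{min_len:.0f} s segment length; returning it whole", stacklevel=2,
        )
        return [replace(rec, data=rec.data.copy())]
    seg_samp = int(round(min_len * rec.fs))
    segments = []
    for k in range(n_seg):
        start = k * seg_samp
        stop = (k + 1) * seg_samp if k < n_seg - 1 else rec.n_samples
        segments.append(replace(rec, data=rec.data[:, start:stop].copy()))
    return segments
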