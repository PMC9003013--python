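"""Synthetic two-group multichannel EEG-like cohorts.

Each channel mixes a shared narrow-band oscillation ``c(t)`` (band-passed
Gaussian noise, so its phase drifts slowly like a physiological rhythm) with an
independent narrow-band oscillation and additive sensor noise:

    s_i(t) = kappa(t) * c_i(t) + (1 - kappa(t)) * o_i(t) + noise_sd * eta_i(t)

where ``c_i`` is the shared source rotated by a small per-channel phase offset
drawn in ``(0, max_phase_offset]``.  The offsets matter: estimators that null
out zero-lag coupling (iCOH, PLI) would see nothing of an instantaneously
mixed source, so a purely zero-lag generator could never exercise them.

The coupling strength ``kappa`` is the group-level control.  On top of the
group mean, each record draws a subject-level offset (people differ) and a slow
temporal modulation (EEG coupling is not stationary); both default to small,
realistic values and can be switched off.

Only relative, ordinal behaviour is claimed of this generator — group
separability and estimator rankings — not physiological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io import EEGRecording, TEN_TWENTY_LABELS, design_bandpass_fir, _zero_phase_filter, write_recording, read_recording

__all__ = ["CohortConfig", "GROUP_LABELS", "generate_record", "generate_cohort",
           "write_cohort", "read_cohort"]

GROUP_LABELS = ("PC", "PE")


@dataclass
class CohortConfig:
    """Study conditions for a synthetic two-group cohort.

    ``n_per_group`` may be a single count (balanced groups) or a
    ``(n_pc, n_pe)`` pair; the default mirrors a 20-control / 16-patient
    clinical cohort.  ``coupling_pc`` / ``coupling_pe`` are the group-mean
    coupling strengths kappa in [0, 1].  ``coupling_tv_sd`` (a scalar or a
    ``(PC, PE)`` pair) sets the slow temporal modulation of kappa: the
    patient group defaults to a much larger value because seizure EEG is
    strongly nonstationary, and that group difference in network *dynamics*
    — not just in mean coupling — is what sliding-window features are meant
    to capture.
    """

    n_per_group: int | tuple = (20, 16)
    n_channels: int = 19
    fs: float = 100.0
    duration: float = 100.0
    coupling_pc: float = 0.3
    coupling_pe: float = 0.6
    band_center: float = 10.0
    band_halfwidth: float = 2.0
    noise_sd: float = 1.0
    max_phase_offset: float = math.pi / 4
    coupling_subject_sd: float = 0.08
    coupling_tv_sd: float | tuple = (0.05, 0.20)
    coupling_tv_timescale: float = 10.0
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_per_group, (int, np.integer)):
            self.n_per_group = (int(self.n_per_group), int(self.n_per_group))
        else:
            self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 2:
            raise ValueError("n_per_group must be >= 2 in each group")
        for name in ("coupling_pc", "coupling_pe"):
            k = getattr(self, name)
            if not 0 <= k <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {k}")
        if isinstance(self.coupling_tv_sd, (int, float)):
            self.coupling_tv_sd = (float(self.coupling_tv_sd),) * 2
        else:
            self.coupling_tv_sd = tuple(float(v) for v in self.coupling_tv_sd)
        if self.fs <= 2 * self.band_center:
            raise ValueError("fs must exceed twice the band centre frequency")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def group_sizes(self) -> dict:
        return dict(zip(GROUP_LABELS, self.n_per_group))

    def coupling(self, group: str) -> float:
        return {"PC": self.coupling_pc, "PE": self.coupling_pe}[group]

    def tv_sd(self, group: str) -> float:
        return dict(zip(GROUP_LABELS, self.coupling_tv_sd))[group]


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      low: float, high: float) -> np.ndarray:
    """Unit-variance band-passed Gaussian noise."""
    taps = design_bandpass_fir(low, high, fs, max_taps=max(33, n // 3))
    x = _zero_phase_filter(rng.standard_normal((1, n)), taps)[0]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    w = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(w / np.sqrt(f), n)
    return x / x.std()


def _ou_modulation(rng: np.random.Generator, n: int, fs: float,
                   timescale: float) -> np.ndarray:
    """Ornstein-Uhlenbeck process with unit stationary SD (slow kappa drift)."""
    dt = 1.0 / fs
    a = math.exp(-dt / timescale)
    b = math.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for t in range(1, n):
        x[t] = a * x[t - 1] + b * eps[t]
    return x


def generate_record(cfg: CohortConfig, group: str, seed: int) -> EEGRecording:
    """One multichannel record of the given group. Deterministic given ``seed``."""
    if group not in GROUP_LABELS:
        raise ValueError(
            f"unknown group {group!r}; allowed labels: {', '.join(GROUP_LABELS)}"
        )
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    low = cfg.band_center - cfg.band_halfwidth
    high = cfg.band_center + cfg.band_halfwidth

    kappa = cfg.coupling(group)
    if cfg.coupling_subject_sd > 0:
        kappa = float(np.clip(kappa + cfg.coupling_subject_sd * rng.standard_normal(),
                              0.0, 1.0))
    tv = cfg.tv_sd(group)
    if tv > 0:
        mod = _ou_modulation(rng, n, cfg.fs, cfg.coupling_tv_timescale)
        kappa_t = np.clip(kappa + tv * mod, 0.0, 1.0)
    else:
        kappa_t = np.full(n, kappa)

    shared = _narrowband_noise(rng, n, cfg.fs, low, high)
    analytic = hilbert(shared)
    if cfg.max_phase_offset > 0:
        offsets = rng.uniform(0.0, cfg.max_phase_offset, size=cfg.n_channels)
    else:
        offsets = np.zeros(cfg.n_channels)

    data = np.empty((cfg.n_channels, n))
    for i in range(cfg.n_channels):
        shared_i = np.real(analytic * np.exp(-1j * offsets[i]))
        own = _narrowband_noise(rng, n, cfg.fs, low, high)
        noise = (_pink_noise(rng, n) if cfg.pink_noise
                 else rng.standard_normal(n))
        data[i] = kappa_t * shared_i + (1.0 - kappa_t) * own + cfg.noise_sd * noise

    labels = (TEN_TWENTY_LABELS if cfg.n_channels == 19
              else [f"CH{i + 1:02d}" for i in range(cfg.n_channels)])
    return EEGRecording(data=data, fs=cfg.fs, channel_labels=labels, group=group)


def generate_cohort(cfg: CohortConfig) -> list[tuple[EEGRecording, str]]:
    """All records of the cohort, with per-record seeds derived from ``cfg.seed``."""
    sizes = cfg.group_sizes()
    total = sum(sizes.values())
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(total) % (2**31)
    out = []
    k = 0
    for group in GROUP_LABELS:
        for j in range(sizes[group]):
            rec = generate_record(cfg, group, int(child_seeds[k]))
            rec.subject_id = f"{group}{j + 1:02d}"
            out.append((rec, group))
            k += 1
    return out


def write_cohort(cohort, outdir, fmt: str = "csv") -> pd.DataFrame:
    """Write records plus a ``manifest.tsv`` (sample_id, group, path)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, group in cohort:
        p = outdir / f"{rec.subject_id}.{fmt}"
        write_recording(rec, p)
        rows.append({"sample_id": rec.subject_id, "group": group,
                     "path": str(p), "fs": rec.fs})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(manifest_path) -> list[tuple[EEGRecording, str]]:
    """Load a cohort back from a manifest written by :func:`write_cohort`."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    out = []
    for _, row in manifest.iterrows():
        rec = read_recording(row["path"], fs_hint=row.get("fs"))
        rec.subject_id = str(row["sample_id"])
        rec.group = str(row["group"])
        out.append((rec, rec.group))
    return out
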