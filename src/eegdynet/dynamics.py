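"""Sliding-window dynamic networks and their summary features.

A 3 s window stepped by 1 s (2/3 overlap) cuts each band-filtered record into
snapshots; each snapshot yields a connectivity matrix, a thresholded graph and
the five topological features, giving five topological time series per record.
Each series is summarised by mean, sample standard deviation (n - 1), median
and interquartile range (linear-interpolation quantiles), giving the 20
dynamic features named ``{stat}-{feature}``.

The threshold proportion is selected once at cohort level — from networks
averaged over participants *and* windows — and reused for every window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import SpectralParams, connectivity_matrix
from .io import BandSpec, EEGRecording
from .metrics import FEATURE_NAMES, StaticFeatures, static_features
from .network import apply_threshold

__all__ = [
    "WindowPlan",
    "TopologySeries",
    "DynamicFeatures",
    "DYNAMIC_FEATURE_NAMES",
    "SUMMARY_STATS",
    "sliding_windows",
    "topology_series",
    "summarize",
    "window_seed",
]

SUMMARY_STATS = ["mean", "sd", "median", "iqr"]

#: the 20 dynamic feature names, feature-major ("mean-small_world", "sd-small_world", ...)
DYNAMIC_FEATURE_NAMES = [f"{s}-{f}" for f in FEATURE_NAMES for s in SUMMARY_STATS]


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window geometry in seconds."""

    width: float = 3.0
    step: float = 1.0

    def __post_init__(self):
        if not 0 < self.step <= self.width:
            raise ValueError("need 0 < step <= width")

    def n_windows(self, duration: float) -> int:
        if duration < self.width:
            raise ValueError(
                f"record of {duration:.1f} s shorter than the {self.width:.1f} s window"
            )
        return int(np.floor((duration - self.width) / self.step + 1e-9)) + 1


@dataclass
class TopologySeries:
    """Per-window topological features in chronological order."""

    times: np.ndarray
    values: list  # of StaticFeatures

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("window times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([v.as_array() for v in self.values])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.feature_matrix(), columns=FEATURE_NAMES)
        df.insert(0, "window_start", self.times)
        df["n_components"] = [v.n_components for v in self.values]
        return df


@dataclass
class DynamicFeatures:
    """The 20 summary features of one record's topological time series."""

    values: dict

    def __post_init__(self):
        missing = [n for n in DYNAMIC_FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"missing dynamic features: {missing}")

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in DYNAMIC_FEATURE_NAMES})


def sliding_windows(rec: EEGRecording, plan: WindowPlan = WindowPlan()
                    ) -> list[EEGRecording]:
    """Windows at starts 0, step, 2*step, ..., each exactly ``width`` seconds.

    A trailing part-window shorter than ``width`` is dropped.
    """
    n_w = plan.n_windows(rec.duration)
    width_samp = int(round(plan.width * rec.fs))
    step_samp = int(round(plan.step * rec.fs))
    out = []
    for k in range(n_w):
        start = k * step_samp
        out.append(replace(rec, data=rec.data[:, start:start + width_samp].copy()))
    return out


def window_seed(base_seed: int, window_index: int) -> int:
    """Deterministic per-window seed for the random-graph baseline."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(window_index),))
    return int(ss.generate_state(1)[0] % (2**31))


def window_matrices(rec: EEGRecording, method: str, band: BandSpec,
                    plan: WindowPlan = WindowPlan(),
                    sp: SpectralParams = SpectralParams()) -> list:
    """One connectivity matrix per sliding window, in chronological order."""
    return [connectivity_matrix(w, method, band, sp)
            for w in sliding_windows(rec, plan)]


def series_from_matrices(mats: list, proportion: float,
                         plan: WindowPlan = WindowPlan(),
                         n_random: int = 20, seed: int = 0) -> TopologySeries:
    """Threshold each window matrix and extract its topological features."""
    import warnings

    times = np.arange(len(mats)) * plan.step
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # summarised below
        for k, mat in enumerate(mats):
            graph = apply_threshold(mat, proportion)
            values.append(static_features(graph, n_random=n_random,
                                          seed=window_seed(seed, k)))
    n_disc = sum(v.n_components > 1 for v in values)
    if n_disc:
        warnings.warn(
            f"{n_disc}/{len(values)} window graphs are disconnected; "
            "path-based metrics used the largest component", stacklevel=2)
    return TopologySeries(times=times, values=values)


def topology_series(rec: EEGRecording, method: str, band: BandSpec,
                    proportion: float, plan: WindowPlan = WindowPlan(),
                    sp: SpectralParams = SpectralParams(),
                    n_random: int = 20, seed: int = 0) -> TopologySeries:
    """Connectivity -> threshold -> features for every sliding window.

    ``proportion`` is the cohort-level threshold selected on the averaged
    dynamic networks; it is applied unchanged to every window.
    """
    mats = window_matrices(rec, method, band, plan, sp)
    return series_from_matrices(mats, proportion, plan, n_random, seed)


def summarize(series: TopologySeries) -> DynamicFeatures:
    """Mean, SD, median and IQR of each topological time series (20 values)."""
    if len(series) < 2:
        raise ValueError("need at least 2 windows to summarise "
                         "(standard deviation undefined)")
    mat = series.feature_matrix()
    out = {}
    for j, feat in enumerate(FEATURE_NAMES):
        col = mat[:, j]
        q75, q25 = np.percentile(col, [75, 25])
        out[f"mean-{feat}"] = float(col.mean())
        out[f"sd-{feat}"] = float(col.std(ddof=1))
        out[f"median-{feat}"] = float(np.median(col))
        out[f"iqr-{feat}"] = float(q75 - q25)
    return DynamicFeatures(values=out)
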