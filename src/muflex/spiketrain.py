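"""Spike-train containers and preprocessing for motor-unit population analysis.

The objects here are the common currency of the package: a :class:`SpikeTrain`
holds the discharge times of one motor unit, a :class:`PopulationRecording`
bundles the concurrently active units of one contraction (optionally with the
torque trace and the plateau segments), and a :class:`SmoothedRateMatrix` is
the units x samples matrix of smoothed firing rates that the latent-factor and
flexibility analyses consume.

Conventions
-----------
* Spike times are continuous seconds; sample indices use round-half-even.
* All analysis windows are half-open ``[start, end)``.
* Smoothed rates are in pulses per second (pps): the Hanning kernel is
  normalized to unit time-integral, so convolving a binary spike train with it
  yields an instantaneous rate estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "PopulationRecording",
    "SmoothedRateMatrix",
    "binarize",
    "smooth_rates",
    "filter_continuous",
    "detrend_concat",
    "find_duplicates",
    "recruitment_threshold",
    "read_spike_csv",
    "write_spike_csv",
    "read_torque_csv",
    "write_torque_csv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Discharge times of a single motor unit.

    Parameters
    ----------
    unit_id : str
        Opaque identifier.
    times : ndarray
        Strictly increasing firing times in seconds.
    source_grid : str, optional
        Label of the electrode grid the unit was decomposed from.
    """

    unit_id: str
    times: np.ndarray
    source_grid: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: times must be 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"unit {self.unit_id}: times must be strictly increasing")
        if t.size and t[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)

    def isi_cov(self) -> float:
        """Coefficient of variation of the ISIs; NaN for < 3 spikes."""
        isi = self.isi()
        if isi.size < 2:
            return float("nan")
        return float(np.std(isi) / np.mean(isi))

    def shifted(self, lag: float) -> "SpikeTrain":
        return replace(self, times=self.times + lag)


@dataclass(frozen=True)
class PopulationRecording:
    """A set of concurrently recorded motor-unit spike trains.

    ``segments`` marks analysis windows (e.g. force plateaus) as half-open
    ``[start, end)`` intervals in seconds; they must be non-overlapping and
    inside ``[0, duration)``.
    """

    trains: tuple[SpikeTrain, ...]
    duration: float
    fs: float = 2048.0
    torque: np.ndarray | None = None
    segments: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for tr in self.trains:
            if tr.times.size and tr.times[-1] > self.duration:
                raise ValueError(
                    f"unit {tr.unit_id}: spike at {tr.times[-1]:.4f} s exceeds "
                    f"duration {self.duration:.4f} s"
                )
        if self.torque is not None:
            object.__setattr__(self, "torque", np.asarray(self.torque, dtype=float))
        if self.segments is not None:
            segs = tuple((float(a), float(b)) for a, b in self.segments)
            prev_end = -np.inf
            for a, b in sorted(segs):
                if not (0.0 <= a < b <= self.duration):
                    raise ValueError(f"segment [{a}, {b}) outside [0, {self.duration})")
                if a < prev_end:
                    raise ValueError("segments overlap")
                prev_end = b
            object.__setattr__(self, "segments", segs)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def unit_ids(self) -> list[str]:
        return [tr.unit_id for tr in self.trains]

    def __getitem__(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)


@dataclass(frozen=True)
class SmoothedRateMatrix:
    """Units x samples matrix of smoothed firing rates (pps)."""

    rates: np.ndarray
    fs: float
    unit_ids: tuple[str, ...]
    detrended: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2:
            raise ValueError("rates must be 2-D (units x samples)")
        if r.shape[0] != len(self.unit_ids):
            raise ValueError("row count must equal len(unit_ids)")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        if not self.detrended and r.size and r.min() < -1e-9:
            raise ValueError("non-detrended rates must be non-negative")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rates.shape[1]

    def downsample(self, factor: int) -> "SmoothedRateMatrix":
        """Decimate by an integer factor (plain subsampling).

        Safe after 400 ms Hanning smoothing (a ~2.5 Hz low-pass) for factors
        keeping the new rate well above 5 Hz.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return replace(self, rates=self.rates[:, ::factor], fs=self.fs / factor)


# ---------------------------------------------------------------------------
# sample-index helpers
# ---------------------------------------------------------------------------


def _sample_index(t, fs: float) -> np.ndarray:
    """Continuous seconds -> sample index, round-half-even."""
    return np.rint(np.asarray(t, dtype=float) * fs).astype(np.int64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def binarize(train: SpikeTrain, fs: float, duration: float) -> np.ndarray:
    """Binary (counting) vector of a spike train at sampling rate ``fs``.

    Element ``j`` holds the number of spikes whose rounded sample index is
    ``j``; values above 1 (two spikes falling in one sample) are permitted but
    logged.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if train.times.size and train.times[-1] > duration:
        raise ValueError(
            f"unit {train.unit_id}: spike at {train.times[-1]:.4f} s exceeds "
            f"duration {duration:.4f} s"
        )
    n = int(round(duration * fs))
    vec = np.zeros(n, dtype=float)
    if train.times.size:
        idx = np.clip(_sample_index(train.times, fs), 0, n - 1)
        np.add.at(vec, idx, 1.0)
        if vec.max() > 1:
            logger.info("unit %s: multiple spikes share a sample at fs=%g", train.unit_id, fs)
    return vec


def _hanning_kernel(kernel_dur: float, fs: float) -> np.ndarray:
    m = int(round(kernel_dur * fs))
    if m < 3:
        raise ValueError("kernel must span at least 3 samples")
    if m % 2 == 0:
        m += 1  # odd length => an exact center sample, zero phase shift
    win = np.hanning(m)
    return win / win.sum() * fs  # unit time-integral -> output in pps


def smooth_rates(
    pop: PopulationRecording, kernel_dur: float = 0.400
) -> SmoothedRateMatrix:
    """Smoothed firing rates: binary trains convolved with a Hanning window.

    The window spans ``kernel_dur`` seconds (default 400 ms, i.e. a ~2.5 Hz
    low-pass retaining the force-related band) and is applied zero-phase
    (centered, zero-padded edges). The kernel integrates to one over time, so
    the output rows are instantaneous firing rates in pps.
    """
    kern = _hanning_kernel(kernel_dur, pop.fs)
    rows = np.empty((pop.n_units, int(round(pop.duration * pop.fs))))
    for i, tr in enumerate(pop.trains):
        vec = binarize(tr, pop.fs, pop.duration)
        rows[i] = signal.fftconvolve(vec, kern, mode="same")
    rows[np.abs(rows) < 1e-12] = 0.0  # fft round-off on empty stretches
    return SmoothedRateMatrix(rows, pop.fs, tuple(pop.unit_ids), detrended=False)


def filter_continuous(
    pop: PopulationRecording,
    window: tuple[float, float] | None = None,
    max_pause: float = 0.400,
) -> PopulationRecording:
    """Keep only units firing continuously throughout ``window``.

    A unit qualifies when every ISI inside the window is <= ``max_pause`` and
    the gaps between the window edges and its first/last in-window spike are
    also <= ``max_pause`` (a unit silent at the start of a plateau is not
    continuously active). With ``window=None`` and ``pop.segments`` set, the
    rule is applied in every segment; otherwise the full recording is used.
    """
    if window is None:
        windows = list(pop.segments) if pop.segments else [(0.0, pop.duration)]
    else:
        a, b = window
        if not (0.0 <= a < b <= pop.duration):
            raise ValueError(f"window [{a}, {b}) outside the recording")
        windows = [(float(a), float(b))]

    def ok(tr: SpikeTrain) -> bool:
        for a, b in windows:
            t = tr.times[(tr.times >= a) & (tr.times < b)]
            if t.size == 0:
                return False
            if t[0] - a > max_pause or b - t[-1] > max_pause:
                return False
            if t.size > 1 and np.max(np.diff(t)) > max_pause:
                return False
        return True

    kept = tuple(tr for tr in pop.trains if ok(tr))
    if not kept:
        warnings.warn("filter_continuous removed every unit", stacklevel=2)
    return replace(pop, trains=kept)


def detrend_concat(
    rm: SmoothedRateMatrix, segments: list[tuple[float, float]] | None = None
) -> SmoothedRateMatrix:
    """Concatenate segments and remove each unit's linear trend.

    Segments (seconds, half-open) are cut from the rate matrix and joined in
    the given order; the least-squares line of each concatenated trace is then
    subtracted, leaving zero-mean, zero-slope residuals.
    """
    if segments is None:
        parts = [rm.rates]
    else:
        n = rm.n_samples
        parts = []
        for a, b in segments:
            i0, i1 = int(round(a * rm.fs)), int(round(b * rm.fs))
            if not (0 <= i0 < i1 <= n):
                raise ValueError(f"segment [{a}, {b}) s outside the rate matrix")
            parts.append(rm.rates[:, i0:i1])
    cat = np.concatenate(parts, axis=1)
    out = signal.detrend(cat, axis=1, type="linear")
    return SmoothedRateMatrix(out, rm.fs, rm.unit_ids, detrended=True)


# -- duplicate detection -----------------------------------------------------


def _best_alignment_lag(a: SpikeTrain, b: SpikeTrain, fs: float, max_lag: float) -> float:
    """Lag (s) to add to ``b`` maximizing binary cross-correlation with ``a``."""
    if a.times.size == 0 or b.times.size == 0:
        return 0.0
    t0 = min(a.times[0], b.times[0])
    dur = max(a.times[-1], b.times[-1]) - t0
    va = np.zeros(int(round(dur * fs)) + 1)
    vb = np.zeros_like(va)
    va[np.clip(_sample_index(a.times - t0, fs), 0, va.size - 1)] = 1.0
    vb[np.clip(_sample_index(b.times - t0, fs), 0, vb.size - 1)] = 1.0
    full = signal.fftconvolve(va, vb[::-1], mode="full")
    lags = np.arange(-(vb.size - 1), va.size)
    m = int(round(max_lag * fs))
    keep = np.abs(lags) <= m
    best = lags[keep][np.argmax(full[keep])]
    return float(best) / fs


def _shared_fraction(ta: np.ndarray, tb: np.ndarray, tol: float) -> float:
    """Fraction of the smaller train's spikes matched within +/- tol."""
    small, big = (ta, tb) if ta.size <= tb.size else (tb, ta)
    if small.size == 0:
        return 0.0
    idx = np.searchsorted(big, small)
    dist = np.full(small.size, np.inf)
    right_ok = idx < big.size
    dist[right_ok] = np.abs(big[idx[right_ok]] - small[right_ok])
    left_ok = idx > 0
    dist[left_ok] = np.minimum(
        dist[left_ok], np.abs(big[idx[left_ok] - 1] - small[left_ok])
    )
    return float(np.mean(dist <= tol))


def find_duplicates(
    trains: list[SpikeTrain],
    tol: float = 0.0005,
    min_share: float = 0.30,
    fs: float = 2048.0,
    align_max_lag: float = 0.020,
) -> tuple[list[list[str]], list[str]]:
    """Identify duplicate motor units decomposed from different grids.

    Each pair is aligned by the integer-sample lag maximizing the binary
    cross-correlation of their spike trains (to absorb action-potential
    propagation delays), then the fraction of the smaller train's spikes
    falling within ``tol`` (default 0.5 ms) of a spike of the other is
    computed. Pairs sharing more than ``min_share`` (default 30%) are
    duplicates; transitive closure yields groups, and within each group the
    unit with the lowest ISI coefficient of variation is retained (ties: more
    spikes, then lexicographic id; units with undefined CoV never win over a
    well-defined one).

    Returns
    -------
    groups : list of list of unit_id
        Duplicate groups with >= 2 members, members sorted.
    retained : list of unit_id
        One representative per group plus all non-duplicated units.
    """
    if len(trains) < 2:
        raise ValueError("need at least two trains")
    n = len(trains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            lag = _best_alignment_lag(trains[i], trains[j], fs, align_max_lag)
            share = _shared_fraction(trains[i].times, trains[j].times + lag, tol)
            if share > min_share:
                parent[find(i)] = find(j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)

    groups: list[list[str]] = []
    retained: list[str] = []
    for idxs in members.values():
        if len(idxs) == 1:
            retained.append(trains[idxs[0]].unit_id)
            continue

        def rank(i: int):
            cov = trains[i].isi_cov()
            return (np.isnan(cov), cov if not np.isnan(cov) else np.inf,
                    -trains[i].n_spikes, trains[i].unit_id)

        keep = min(idxs, key=rank)
        groups.append(sorted(trains[i].unit_id for i in idxs))
        retained.append(trains[keep].unit_id)
    groups.sort()
    retained.sort()
    return groups, retained


def recruitment_threshold(
    train: SpikeTrain,
    torque: np.ndarray,
    fs: float,
    max_span: float = 1.0,
) -> float:
    """Recruitment threshold of a unit in %MVC.

    Recruitment time is the first firing of a series of three firings within
    ``max_span`` seconds (``t_{i+2} - t_i <= max_span``); the threshold is the
    torque sample at that time. Returns NaN when no qualifying triple exists.
    """
    torque = np.asarray(torque, dtype=float)
    t = train.times
    if t.size and torque.size <= _sample_index(t[-1], fs):
        raise ValueError("torque series does not cover the spike train")
    for i in range(t.size - 2):
        if t[i + 2] - t[i] <= max_span:
            return float(torque[_sample_index(t[i], fs)])
    return float("nan")


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------


def read_spike_csv(path) -> list[SpikeTrain]:
    """Read spike trains from CSV with header ``unit_id,time_s[,grid]``."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns or "time_s" not in df.columns:
        raise ValueError("spike CSV must have columns unit_id,time_s[,grid]")
    has_grid = "grid" in df.columns
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        grid = str(grp["grid"].iloc[0]) if has_grid and grp["grid"].notna().any() else None
        trains.append(SpikeTrain(str(uid), np.sort(grp["time_s"].to_numpy(float)), grid))
    return trains


def write_spike_csv(trains: list[SpikeTrain], path) -> None:
    frames = []
    for tr in trains:
        d = {"unit_id": tr.unit_id, "time_s": tr.times}
        if tr.source_grid is not None:
            d["grid"] = tr.source_grid
        frames.append(pd.DataFrame(d))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit_id", "time_s"]
    )
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_torque_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a torque trace CSV ``time_s,torque_pct_mvc`` -> (time, torque)."""
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(float), df["torque_pct_mvc"].to_numpy(float)


def write_torque_csv(time_s: np.ndarray, torque: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": time_s, "torque_pct_mvc": torque}).to_csv(
        path, index=False, lineterminator="\n", encoding="utf-8"
    )
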