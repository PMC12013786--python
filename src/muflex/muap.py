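"""MUAP templates, amplitude maps and motor-unit localization on HD-sEMG grids.

A motor unit's surface action potential (MUAP) is estimated by
spike-triggered averaging of single-differential EMG over 50 ms windows. The
peak-to-peak amplitude of each channel's template gives a 12 x 5 amplitude
map per grid (13 electrode rows differentiated along columns); a 3 x 3 box
blur suppresses single-channel artifacts, and the unit is localized at the
global-argmax electrode across grids. Distances between units are Euclidean
in a common millimetre frame in which successive grids lie along the muscle
axis separated edge-to-edge by a configurable inter-grid gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .spiketrain import SpikeTrain

__all__ = [
    "GridLayout",
    "MUAPTemplate",
    "UnitLocation",
    "spike_triggered_average",
    "amplitude_map",
    "locate_unit",
    "locate_and_distance",
]


@dataclass(frozen=True)
class GridLayout:
    """Geometry of one or more 13 x 5 electrode grids.

    ``inter_electrode`` is the electrode pitch in mm (8 for the vastus
    grids, 4 for gastrocnemius). Grids are assumed coplanar and collinear
    along the muscle (row) axis, separated edge-to-edge by ``inter_grid`` mm.
    Differential maps have ``rows - 1`` rows.
    """

    rows: int = 13
    cols: int = 5
    inter_electrode: float = 8.0
    n_grids: int = 4
    inter_grid: float = 24.0

    def __post_init__(self):
        if self.inter_electrode <= 0:
            raise ValueError("inter_electrode must be positive")

    @property
    def diff_rows(self) -> int:
        return self.rows - 1

    def position(self, grid: int, row: int, col: int) -> np.ndarray:
        """mm position of a differential site (midpoint of its electrode pair)."""
        if not (0 <= grid < self.n_grids):
            raise ValueError(f"grid {grid} out of range")
        if not (0 <= row < self.diff_rows and 0 <= col < self.cols):
            raise ValueError(f"site ({row}, {col}) outside the differential map")
        grid_span = (self.rows - 1) * self.inter_electrode
        y = grid * (grid_span + self.inter_grid) + (row + 0.5) * self.inter_electrode
        x = col * self.inter_electrode
        return np.array([x, y])


@dataclass(frozen=True)
class MUAPTemplate:
    """Spike-triggered-average waveforms, (diff_rows x cols x window samples)."""

    waveforms: np.ndarray
    fs: float
    unit_id: str
    n_spikes_used: int
    n_spikes_skipped: int = 0

    def __post_init__(self):
        w = np.asarray(self.waveforms, dtype=float)
        if w.ndim != 3:
            raise ValueError("waveforms must be rows x cols x samples")
        object.__setattr__(self, "waveforms", w)


@dataclass(frozen=True)
class UnitLocation:
    grid: int
    electrode: tuple[int, int]   # (row, col) in the differential map
    position_mm: np.ndarray


def spike_triggered_average(
    emg: np.ndarray,
    train: SpikeTrain,
    fs: float,
    window: float = 0.050,
    grid_shape: tuple[int, int] = (12, 5),
) -> MUAPTemplate:
    """Average 50 ms EMG windows centred on each firing time.

    ``emg`` is channels x samples with channels in row-major grid order.
    Spikes whose window would be truncated by the recording edges are
    skipped (and counted in ``n_spikes_skipped``).
    """
    emg = np.asarray(emg, dtype=float)
    n_ch, n_samp = emg.shape
    rows, cols = grid_shape
    if rows * cols != n_ch:
        raise ValueError(f"{n_ch} channels do not form a {rows}x{cols} grid")
    w = int(round(window * fs))
    if w % 2 == 0:
        w += 1
    half = w // 2
    acc = np.zeros((n_ch, w))
    used = skipped = 0
    for t in train.times:
        i = int(round(t * fs))
        if i - half < 0 or i + half + 1 > n_samp:
            skipped += 1
            continue
        acc += emg[:, i - half:i + half + 1]
        used += 1
    if used == 0:
        raise ValueError(f"unit {train.unit_id}: no spike with a full window")
    return MUAPTemplate(
        waveforms=(acc / used).reshape(rows, cols, w),
        fs=fs,
        unit_id=train.unit_id,
        n_spikes_used=used,
        n_spikes_skipped=skipped,
    )


def amplitude_map(tpl: MUAPTemplate | np.ndarray, blur: bool = True,
                  edge_mode: str = "zero") -> np.ndarray:
    """Peak-to-peak amplitude per channel, optionally 3 x 3 box-blurred.

    ``edge_mode`` controls the blur boundary rule. ``"zero"`` (default) is a
    plain zero-padded convolution: it preserves the argmax for any source
    centred off the outermost row/column (a source one site in from the edge
    is the worst case for the alternative). ``"normalized"`` renormalizes the
    kernel over in-bounds neighbours, which leaves constant maps unchanged
    but systematically pulls the argmax of near-edge sources onto the edge.
    """
    if isinstance(tpl, MUAPTemplate):
        amp = tpl.waveforms.max(axis=2) - tpl.waveforms.min(axis=2)
    else:
        amp = np.asarray(tpl, dtype=float)
    if not blur:
        return amp
    kern = np.ones((3, 3))
    num = convolve2d(amp, kern, mode="same")
    if edge_mode == "zero":
        return num / kern.size
    if edge_mode == "normalized":
        den = convolve2d(np.ones_like(amp), kern, mode="same")
        return num / den
    raise ValueError(f"unknown edge_mode {edge_mode!r}")


def locate_unit(maps: list[np.ndarray], layout: GridLayout) -> UnitLocation:
    """Locate a unit at the global-argmax electrode across its grid maps."""
    if len(maps) != layout.n_grids:
        raise ValueError(f"expected {layout.n_grids} maps, got {len(maps)}")
    best = None
    for g, m in enumerate(maps):
        m = np.asarray(m, dtype=float)
        if m.shape != (layout.diff_rows, layout.cols):
            raise ValueError(f"map {g} has shape {m.shape}, expected "
                             f"{(layout.diff_rows, layout.cols)}")
        r, c = np.unravel_index(int(np.argmax(m)), m.shape)
        val = m[r, c]
        if best is None or val > best[0]:
            best = (val, g, int(r), int(c))
        elif val == best[0]:
            warnings.warn("amplitude tie at argmax; keeping lowest (grid,row,col)",
                          stacklevel=2)
    _, g, r, c = best
    return UnitLocation(grid=g, electrode=(r, c),
                        position_mm=layout.position(g, r, c))


def locate_and_distance(
    maps_a: list[np.ndarray], maps_b: list[np.ndarray], layout: GridLayout
) -> float:
    """Euclidean mm distance between two units' argmax electrodes."""
    la = locate_unit(maps_a, layout)
    lb = locate_unit(maps_b, layout)
    return float(np.linalg.norm(la.position_mm - lb.position_mm))
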