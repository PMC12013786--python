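"""Displacement and dispersion: deviation from a 1-D monotonic rate manifold.

A population of motor units driven purely by one common input moves along a
one-dimensional monotonic manifold: when the drive rises, every unit's rate
rises (or stays at zero/saturation). The two statistics here quantify
violations of that picture for a pair of units:

* **Displacement** — for each ordered pair of time points (t, t'), the
  maximal non-negative rate change ``dr(t, t') = max_i (r_i(t) - r_i(t'))``
  is computed in both directions; if all units move together one direction is
  <= 0, so ``min(dr(t, t'), dr(t', t))`` is positive only when two units move
  in opposite directions. Displacement is the maximum of that quantity over
  all time pairs.

* **Dispersion** — the L1 population norm ``|r(t)|_1`` of a 1-D-driven
  population indexes a unique population state, so two times with the same
  norm must show the same rate distribution. Dispersion is the largest L1
  distance ``|r(t1) - r(t2)|_1`` over time pairs whose norms agree (within a
  small tolerance bin).

Both metrics are minimized over a per-unit integer-sample lag grid of up to
``max_lag`` (default 25 ms) to discount apparent flexibility caused by
conduction-velocity differences, and can be normalized by the summed maximum
rates of the pair to compare across tasks and muscles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spiketrain import SmoothedRateMatrix

__all__ = [
    "RateEnsemble",
    "FlexibilityResult",
    "pair_displacement",
    "pair_dispersion",
    "pair_flexibility",
    "population_pairwise",
]


@dataclass(frozen=True)
class RateEnsemble:
    """Smoothed rates (pps) of n >= 2 units on a common time base."""

    rates: np.ndarray
    fs: float
    unit_ids: tuple[str, ...]

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2 or r.shape[0] < 1:
            raise ValueError("rates must be units x samples")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))

    @classmethod
    def from_rate_matrix(cls, rm: SmoothedRateMatrix) -> "RateEnsemble":
        return cls(rm.rates, rm.fs, rm.unit_ids)


@dataclass(frozen=True)
class FlexibilityResult:
    """Raw and normalized flexibility metrics for one unit pair."""

    pair: tuple[str, str]
    displacement_raw: float      # pps
    dispersion_raw: float        # pps
    displacement_norm: float     # raw / sum of per-unit max rates
    dispersion_norm: float
    best_lags_displacement: tuple[float, float]  # s, per unit
    best_lags_dispersion: tuple[float, float]


def _lag_grid(max_lag: float, fs: float, n_samples: int) -> list[int]:
    m = int(round(max_lag * fs))
    if 2 * m + 1 >= n_samples:
        raise ValueError("lag grid exceeds series length")
    return list(range(-m, m + 1))


def _shift_pair(r: np.ndarray, l1: int, l2: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-unit integer lags, keeping the common valid overlap."""
    T = r.shape[1]
    start = max(0, -l1, -l2)
    stop = T - max(0, l1, l2)
    return r[0, start + l1:stop + l1], r[1, start + l2:stop + l2]


def _displacement_at(r1: np.ndarray, r2: np.ndarray) -> float:
    d1 = r1[:, None] - r1[None, :]
    d2 = r2[:, None] - r2[None, :]
    delta = np.maximum(d1, d2)           # dr(t, t') for every ordered pair
    cand = np.minimum(delta, delta.T)    # min of the two directions
    return float(cand.max())             # diagonal gives >= 0


def _dispersion_at(r1: np.ndarray, r2: np.ndarray, norm_tol: float) -> float:
    norms = np.abs(r1) + np.abs(r2)
    match = np.abs(norms[:, None] - norms[None, :]) <= norm_tol
    if not match.any():
        return 0.0
    diff = np.abs(r1[:, None] - r1[None, :]) + np.abs(r2[:, None] - r2[None, :])
    return float(diff[match].max())


def _norm_tol(r: np.ndarray, rel: float) -> float:
    norms = np.abs(r).sum(axis=0)
    return rel * float(norms.max() - norms.min())


def pair_flexibility(
    ens: RateEnsemble,
    max_lag: float = 0.025,
    norm_tol: float | None = None,
    norm_tol_rel: float = 0.005,
    decimate: int = 1,
) -> FlexibilityResult:
    """Displacement and dispersion for a pair of units.

    Per-unit lags are constant integer-sample shifts searched on the grid
    ``[-max_lag, +max_lag]`` and chosen (independently per metric) to
    minimize it. ``norm_tol`` is the absolute norm-matching tolerance for
    dispersion; by default it is ``norm_tol_rel`` (0.5%) of the norm range.
    ``decimate`` subsamples the time axis for long series (exactness is only
    guaranteed at decimate=1).
    """
    if ens.rates.shape[0] != 2:
        raise ValueError("pair metrics need exactly 2 units")
    r = ens.rates[:, ::decimate] if decimate > 1 else ens.rates
    fs = ens.fs / decimate
    lags = _lag_grid(max_lag, fs, r.shape[1])
    if norm_tol is None:
        norm_tol = _norm_tol(r, norm_tol_rel)

    best_disp = np.inf
    best_dispersion = np.inf
    best_lag_disp = (0, 0)
    best_lag_dispersion = (0, 0)
    for l1 in lags:
        for l2 in lags:
            r1, r2 = _shift_pair(r, l1, l2)
            d = _displacement_at(r1, r2)
            if d < best_disp:
                best_disp, best_lag_disp = d, (l1, l2)
            s = _dispersion_at(r1, r2, norm_tol)
            if s < best_dispersion:
                best_dispersion, best_lag_dispersion = s, (l1, l2)

    denom = float(ens.rates[0].max() + ens.rates[1].max())
    if denom <= 0:
        warnings.warn("zero maximum rates: normalized metrics undefined, using 0",
                      stacklevel=2)
        dn = sn = 0.0
    else:
        dn = best_disp / denom
        sn = best_dispersion / denom
    return FlexibilityResult(
        pair=(ens.unit_ids[0], ens.unit_ids[1]),
        displacement_raw=best_disp,
        dispersion_raw=best_dispersion,
        displacement_norm=dn,
        dispersion_norm=sn,
        best_lags_displacement=(best_lag_disp[0] / fs, best_lag_disp[1] / fs),
        best_lags_dispersion=(best_lag_dispersion[0] / fs,
                              best_lag_dispersion[1] / fs),
    )


def pair_displacement(ens: RateEnsemble, max_lag: float = 0.025, **kw) -> FlexibilityResult:
    """Displacement for a 2-unit ensemble (full result; see pair_flexibility)."""
    return pair_flexibility(ens, max_lag=max_lag, **kw)


def pair_dispersion(
    ens: RateEnsemble, max_lag: float = 0.025, norm_tol: float | None = None, **kw
) -> FlexibilityResult:
    """Dispersion for a 2-unit ensemble (full result; see pair_flexibility)."""
    return pair_flexibility(ens, max_lag=max_lag, norm_tol=norm_tol, **kw)


def population_pairwise(
    rates: RateEnsemble | SmoothedRateMatrix,
    pairs: str | list[tuple[str, str]] = "all",
    max_lag: float = 0.025,
    **kw,
) -> pd.DataFrame:
    """Flexibility metrics for all (or selected) unordered unit pairs.

    Returns a DataFrame with one row per pair in lexicographic id order and
    columns ``unit_a, unit_b, displacement_pps, dispersion_pps,
    displacement_norm, dispersion_norm``.
    """
    if isinstance(rates, SmoothedRateMatrix):
        rates = RateEnsemble.from_rate_matrix(rates)
    if rates.rates.shape[0] < 2:
        raise ValueError("need at least 2 units")
    ids = list(rates.unit_ids)
    index = {u: i for i, u in enumerate(ids)}
    if pairs == "all":
        todo = list(itertools.combinations(sorted(ids), 2))
    else:
        todo = sorted(tuple(sorted(p)) for p in pairs)
    rows = []
    for a, b in todo:
        sub = RateEnsemble(rates.rates[[index[a], index[b]]], rates.fs, (a, b))
        res = pair_flexibility(sub, max_lag=max_lag, **kw)
        rows.append({
            "unit_a": a,
            "unit_b": b,
            "displacement_pps": res.displacement_raw,
            "dispersion_pps": res.dispersion_raw,
            "displacement_norm": res.displacement_norm,
            "dispersion_norm": res.dispersion_norm,
        })
    return pd.DataFrame(rows)
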