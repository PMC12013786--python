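"""Latent-factor dimensionality of motor-unit smoothed firing rates.

The pipeline: maximum-likelihood factor analysis on the unit-by-unit
correlation matrix of detrended smoothed rates, promax (oblique) rotation,
reconstruction R² as a function of the number of factors k, and selection of
the latent dimensionality by comparing the R² curve of the data against that
of a surrogate population in which each unit's inter-spike intervals are
randomly permuted (destroying shared low-frequency structure while preserving
spike count and mean rate exactly).

Three selection rules are provided:

* ``k_slope`` — surrogate-slope rule: the largest k such that the forward
  difference of the data R² curve exceeds the straight-line slope of the
  surrogate R² curve at every smaller k (minimum 1).
* ``k_5pct`` — first k beyond which the R² increase falls below 5 points.
* ``k_mse`` — first k from which a straight-line fit to the remaining R²
  curve has mean squared error below 1e-3 (plateau rule).

`LatentFactorModel` and `DimensionalitySelector` follow scikit-learn
estimator conventions (``fit``, ``transform``, trailing-underscore fitted
attributes) and compose with sklearn tooling; the module-level functions are
thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.multivariate.factor_rotation import rotate_factors

from .spiketrain import (
    PopulationRecording,
    SmoothedRateMatrix,
    detrend_concat,
    smooth_rates,
)

__all__ = [
    "FactorModel",
    "DimensionalityReport",
    "LatentFactorModel",
    "DimensionalitySelector",
    "fit_factor_model",
    "reconstruction_r2",
    "surrogate_population",
    "select_dimensionality",
    "dominant_factor_clusters",
]

UNIQUENESS_FLOOR = 0.005  # Heywood-case clamp on the correlation scale


def ledermann_bound(p: int) -> int:
    """Largest admissible factor count for p variables.

    The identifiability requirement (p - k)^2 >= p + k, relaxed to always
    admit the single-factor model (computable, if saturated, down to p = 2).
    """
    k = 0
    while k + 1 < p and (p - (k + 1)) ** 2 >= p + (k + 1):
        k += 1
    return max(k, 1) if p >= 2 else 0


def _promax(A: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax rotation: varimax, then oblique Procrustes to a powered target.

    Returns the rotated (pattern) loadings and the factor correlation matrix.
    """
    if A.shape[1] == 1:
        return A.copy(), np.ones((1, 1))
    V, _ = rotate_factors(A, "varimax")
    Q = np.abs(V) ** power * np.sign(V)
    U, *_ = np.linalg.lstsq(V, Q, rcond=None)
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d  # scale so factors keep unit variance
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def _ml_factor(R: np.ndarray, k: int, max_iter: int = 1000,
               psi_floor: float = UNIQUENESS_FLOOR) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Maximum-likelihood factor fit of a correlation matrix.

    Profile likelihood over the uniquenesses (the loadings given the
    uniquenesses follow from the top-k eigenpairs of the rescaled
    correlation matrix); L-BFGS-B with the analytic gradient.

    Returns (loadings p x k, uniquenesses, n_iterations, converged).
    """
    p = R.shape[0]

    def eig(psi):
        sc = 1.0 / np.sqrt(psi)
        vals, vecs = np.linalg.eigh(R * np.outer(sc, sc))
        return vals[::-1], vecs[:, ::-1]

    def objective(psi):
        vals, _ = eig(psi)
        e = vals[k:]
        return -(np.sum(np.log(e) - e) + k - p)

    def gradient(psi):
        vals, vecs = eig(psi)
        lam = np.sqrt(np.maximum(vals[:k] - 1.0, 0.0))
        load = np.sqrt(psi)[:, None] * (vecs[:, :k] * lam)
        g = np.sum(load ** 2, axis=1) + psi - np.diag(R)
        return g / psi ** 2

    inv_diag = np.diag(np.linalg.pinv(R))
    psi0 = np.clip((1.0 - 0.5 * k / p) / np.maximum(inv_diag, 1.0), psi_floor, 1.0)
    res = minimize(objective, psi0, jac=gradient, method="L-BFGS-B",
                   bounds=[(psi_floor, 1.0)] * p,
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
    psi = res.x
    vals, vecs = eig(psi)
    lam = np.sqrt(np.maximum(vals[:k] - 1.0, 0.0))
    load = np.sqrt(psi)[:, None] * (vecs[:, :k] * lam)
    # orient each factor so its largest loading is positive (sign convention)
    for j in range(k):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    return load, psi, int(res.nit), bool(res.success)


@dataclass(frozen=True)
class FactorModel:
    """Fitted factor-analysis model on the correlation scale."""

    loadings: np.ndarray          # units x k, promax pattern matrix
    uniquenesses: np.ndarray      # per-unit residual variances
    factor_scores: np.ndarray     # k x samples (regression estimator)
    phi: np.ndarray               # k x k factor correlation
    rotation: str
    k: int
    unit_ids: tuple[str, ...]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class DimensionalityReport:
    """R² curves and the dimensionality selected by each criterion."""

    r2_data: np.ndarray        # R² for k = 1..kmax
    r2_surrogate: np.ndarray
    k_slope: int
    k_5pct: int
    k_mse: int
    surrogate_seed: int
    surrogate_slope: float


class FactorAnalysisError(RuntimeError):
    pass


class LatentFactorModel(TransformerMixin, BaseEstimator):
    """Maximum-likelihood factor analysis with promax rotation.

    Operates on the correlation scale: columns of X (samples x units) are
    z-scored before the ML fit, so loadings are correlations between units
    and factors. Factor scores use the regression (Thomson) estimator.

    Parameters
    ----------
    n_factors : int
        Number of latent factors.
    rotation : {"promax", "varimax", None}
        Rotation applied to the ML solution. Promax (oblique, power
        ``promax_power``) is the default.
    promax_power : int
        Power of the promax target matrix.
    max_iter : int
        Iteration cap of the uniqueness optimization.
    """

    def __init__(
        self,
        n_factors: int = 1,
        rotation: str | None = "promax",
        promax_power: int = 4,
        max_iter: int = 1000,
    ):
        self.n_factors = n_factors
        self.rotation = rotation
        self.promax_power = promax_power
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x units")
        n, p = X.shape
        k = int(self.n_factors)
        if k < 1:
            raise ValueError("n_factors must be >= 1")
        if k > ledermann_bound(p):
            raise FactorAnalysisError(
                f"n_factors={k} exceeds the identifiability bound "
                f"{ledermann_bound(p)} for {p} units"
            )
        if n <= p:
            warnings.warn("fewer samples than units: FA fit is ill-conditioned",
                          stacklevel=2)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise FactorAnalysisError("constant unit trace: correlation undefined")
        Z = (X - mu) / sd

        R = np.corrcoef(Z, rowvar=False)
        A, psi, n_iter, converged = _ml_factor(R, k, max_iter=self.max_iter)
        if not converged:
            raise FactorAnalysisError(
                f"ML factor analysis did not converge in {n_iter} iterations")
        if np.any(psi <= UNIQUENESS_FLOOR + 1e-12):
            warnings.warn("Heywood case: uniqueness clamped at floor", stacklevel=2)

        if self.rotation is None or k == 1:
            L, phi = A.copy(), np.eye(k)
        elif self.rotation == "promax":
            L, phi = _promax(A, self.promax_power)
        elif self.rotation == "varimax":
            L, _ = rotate_factors(A, "varimax")
            phi = np.eye(k)
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")

        self.n_iter_ = n_iter
        self.mean_ = mu
        self.scale_ = sd
        self.loadings_ = L
        self.uniquenesses_ = psi
        self.phi_ = phi
        # regression scores: F = Z R^-1 S with structure S = pattern @ phi;
        # use the model-implied correlation for stability
        R = A @ A.T + np.diag(psi)
        self._score_weights = np.linalg.solve(R, L @ phi)
        return self

    def transform(self, X) -> np.ndarray:
        """Regression-estimator factor scores, samples x k."""
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self._score_weights

    def reconstruction_r2(self, X) -> float:
        """Pooled R² between reconstructed and original standardized rates."""
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        Zhat = self.transform(X) @ self.loadings_.T
        sse = float(np.sum((Z - Zhat) ** 2))
        sst = float(np.sum((Z - Z.mean(axis=0)) ** 2))
        return max(0.0, min(1.0, 1.0 - sse / sst))


# ---------------------------------------------------------------------------
# functional wrappers on the package's rate-matrix container
# ---------------------------------------------------------------------------


def fit_factor_model(rm: SmoothedRateMatrix, k: int, **kwargs) -> FactorModel:
    """Fit a promax-rotated ML factor model to a detrended rate matrix."""
    if not rm.detrended:
        raise ValueError("factor analysis expects detrended rates")
    est = LatentFactorModel(n_factors=k, **kwargs).fit(rm.rates.T)
    scores = est.transform(rm.rates.T).T
    return FactorModel(
        loadings=est.loadings_,
        uniquenesses=est.uniquenesses_,
        factor_scores=scores,
        phi=est.phi_,
        rotation=est.rotation or "none",
        k=k,
        unit_ids=rm.unit_ids,
    )


def reconstruction_r2(model: FactorModel, rm: SmoothedRateMatrix) -> float:
    """R² of the rank-k reconstruction of the standardized rate matrix."""
    X = rm.rates.T
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd
    Zhat = model.factor_scores.T @ model.loadings.T
    sse = float(np.sum((Z - Zhat) ** 2))
    sst = float(np.sum((Z - Z.mean(axis=0)) ** 2))
    return max(0.0, min(1.0, 1.0 - sse / sst))


def surrogate_population(pop: PopulationRecording, seed: int) -> PopulationRecording:
    """ISI-shuffled surrogate: same spike counts and mean rates, no shared drive.

    Per unit, the sequence of inter-spike intervals is randomly permuted and
    re-cumulated from the original first spike, so the spike count, first and
    last spike times, and hence the mean firing rate are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    new = []
    for tr in pop.trains:
        if tr.n_spikes < 3:
            new.append(tr)
            continue
        isi = rng.permutation(tr.isi())
        times = tr.times[0] + np.concatenate(([0.0], np.cumsum(isi)))
        new.append(replace(tr, times=times))
    return replace(pop, trains=tuple(new))


def _default_preprocess(pop: PopulationRecording, rm: SmoothedRateMatrix,
                        kernel_dur: float) -> SmoothedRateMatrix:
    """Mirror the data pipeline (smooth -> detrend/concat -> downsample)."""
    sm = smooth_rates(pop, kernel_dur=kernel_dur)
    out = detrend_concat(sm, list(pop.segments) if pop.segments else None)
    factor = int(round(pop.fs / rm.fs))
    if factor > 1:
        out = out.downsample(factor)
    return out


class DimensionalitySelector(BaseEstimator):
    """Latent dimensionality of a motor-unit population by three criteria.

    ``fit`` takes the detrended rate matrix together with the spike-train
    population it came from (needed to build the ISI-shuffled surrogate) and
    exposes the selected counts as fitted attributes ``k_slope_``,
    ``k_5pct_``, ``k_mse_`` plus the full ``report_``.

    Parameters
    ----------
    kmax : int
        Largest factor count scanned (>= 2).
    seed : int
        Seed of the single surrogate realization.
    kernel_dur : float
        Hanning-kernel duration used when re-smoothing the surrogate.
    data_slope : {"pointwise", "fitted"}
        Whether the data R² slope is the discrete forward difference
        (default) or the slope of a least-squares line through the whole
        curve. The surrogate slope is always the fitted-line slope.
    """

    def __init__(self, kmax: int = 10, seed: int = 0, kernel_dur: float = 0.400,
                 data_slope: str = "pointwise", rotation: str = "promax"):
        self.kmax = kmax
        self.seed = seed
        self.kernel_dur = kernel_dur
        self.data_slope = data_slope
        self.rotation = rotation

    def _r2_curve(self, rm: SmoothedRateMatrix) -> np.ndarray:
        r2 = []
        for k in range(1, self.kmax + 1):
            try:
                model = fit_factor_model(rm, k, rotation=self.rotation)
            except FactorAnalysisError as err:
                warnings.warn(
                    f"factor analysis failed at k={k} ({err}); "
                    "excluding this and larger k", stacklevel=2)
                break
            r2.append(reconstruction_r2(model, rm))
        if not r2:
            raise FactorAnalysisError("factor analysis failed at every k")
        return np.asarray(r2)

    def fit(self, rm: SmoothedRateMatrix, pop: PopulationRecording,
            preprocess=None):
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")
        if preprocess is None:
            sur_rm = _default_preprocess(
                surrogate_population(pop, self.seed), rm, self.kernel_dur)
        else:
            sur_rm = preprocess(surrogate_population(pop, self.seed))

        r2_data = self._r2_curve(rm)
        r2_sur = self._r2_curve(sur_rm)
        m = min(r2_data.size, r2_sur.size)
        r2_data, r2_sur = r2_data[:m], r2_sur[:m]

        ks = np.arange(1, m + 1)
        sur_slope = float(np.polyfit(ks, r2_sur, 1)[0])

        if self.data_slope == "fitted":
            data_slopes = np.full(m - 1, float(np.polyfit(ks, r2_data, 1)[0]))
        else:
            data_slopes = np.diff(r2_data)
        run = 0
        for s in data_slopes:
            if s > sur_slope:
                run += 1
            else:
                break
        k_slope = min(1 + run, self.kmax - 1)

        diffs = np.diff(r2_data)
        k_5pct = m if diffs.size == 0 else (
            int(np.argmax(diffs < 0.05)) + 1 if np.any(diffs < 0.05) else m)

        k_mse = m
        for k in range(1, m + 1):
            tail = r2_data[k - 1:]
            if tail.size < 2:
                mse = 0.0
            else:
                kk = np.arange(tail.size)
                resid = tail - np.polyval(np.polyfit(kk, tail, 1), kk)
                mse = float(np.mean(resid ** 2))
            if mse < 1e-3:
                k_mse = k
                break

        self.r2_data_ = r2_data
        self.r2_surrogate_ = r2_sur
        self.surrogate_slope_ = sur_slope
        self.k_slope_ = int(k_slope)
        self.k_5pct_ = int(k_5pct)
        self.k_mse_ = int(k_mse)
        self.report_ = DimensionalityReport(
            r2_data=r2_data, r2_surrogate=r2_sur, k_slope=self.k_slope_,
            k_5pct=self.k_5pct_, k_mse=self.k_mse_,
            surrogate_seed=self.seed, surrogate_slope=sur_slope)
        return self


def select_dimensionality(
    rm: SmoothedRateMatrix,
    pop: PopulationRecording,
    kmax: int = 10,
    seed: int = 0,
    **kwargs,
) -> DimensionalityReport:
    """Select the latent dimensionality of ``rm`` (see DimensionalitySelector)."""
    sel = DimensionalitySelector(kmax=kmax, seed=seed, **kwargs).fit(rm, pop)
    return sel.report_


def dominant_factor_clusters(model: FactorModel) -> dict[str, int]:
    """Assign each unit to its dominant factor (argmax |loading|, 0-based).

    Ties break toward the lowest factor index.
    """
    labels = {}
    for uid, row in zip(model.unit_ids, model.loadings):
        labels[uid] = int(np.argmax(np.abs(row)))
    return labels
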