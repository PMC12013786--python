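"""Factor analysis, reconstruction R², surrogates and dimensionality selection."""

import numpy as np
import pytest

from muflex.dimensionality import (
    DimensionalitySelector,
    FactorAnalysisError,
    dominant_factor_clusters,
    fit_factor_model,
    ledermann_bound,
    reconstruction_r2,
    select_dimensionality,
    surrogate_population,
)
from muflex.spiketrain import (
    PopulationRecording,
    SmoothedRateMatrix,
    SpikeTrain,
    detrend_concat,
    filter_continuous,
    smooth_rates,
)
from muflex.synthetic import LatentPopulationSpec, latent_population, lowpass_gaussian


def _rm(rates, fs=64.0):
    ids = tuple(f"u{i}" for i in range(rates.shape[0]))
    return SmoothedRateMatrix(np.asarray(rates, float), fs, ids, detrended=True)


def standard_pipeline(pop, downsample=32):
    """Smooth, detrend over an interior window, downsample — shared by tests."""
    a, b = 0.5, pop.duration - 0.5
    pop = PopulationRecording(pop.trains, pop.duration, pop.fs, segments=((a, b),))
    pop = filter_continuous(pop)
    rm = detrend_concat(smooth_rates(pop), list(pop.segments))
    return pop, rm.downsample(downsample)


class TestFactorModel:
    def test_identical_traces_load_fully_on_one_factor(self, rng):
        sig = lowpass_gaussian(2000, 64.0, 2.5, rng)[0]
        noise = 0.01 * rng.standard_normal((2, 2000))
        m = fit_factor_model(_rm(np.vstack([sig, sig]) + noise), 1)
        assert np.all(np.abs(m.loadings) > 0.99)

    def test_heterogeneous_latents_recovered(self):
        hits = 0
        for seed in range(3):
            spec = LatentPopulationSpec(seed=seed, duration=40.0)
            pop, truth = latent_population(spec)
            pop, rm = standard_pipeline(pop)
            m = fit_factor_model(rm, 3)
            # map latents onto the analysis grid
            t = np.arange(rm.n_samples) / rm.fs + 0.5
            tt = np.arange(truth["latents"].shape[1]) / truth["truth_fs"]
            lat = np.vstack([np.interp(t, tt, l) for l in truth["latents"]])
            c = np.abs(np.corrcoef(m.factor_scores, lat)[:3, 3:])
            # greedy sign/permutation matching
            matched = sorted(c.max(axis=1), reverse=True)
            hits += all(v > 0.9 for v in matched)
        assert hits >= 2

    def test_k_above_identifiability_bound_errors(self, rng):
        X = rng.standard_normal((5, 500))
        with pytest.raises(FactorAnalysisError, match="identifiability"):
            fit_factor_model(_rm(X), ledermann_bound(5) + 1)

    def test_requires_detrended_input(self, rng):
        rm = SmoothedRateMatrix(np.abs(rng.standard_normal((3, 100))), 64.0,
                                ("a", "b", "c"), detrended=False)
        with pytest.raises(ValueError, match="detrended"):
            fit_factor_model(rm, 1)


class TestReconstructionR2:
    def test_rank_one_noiseless_data(self, rng):
        sig = lowpass_gaussian(3000, 64.0, 2.5, rng)[0]
        weights = np.array([1.0, 2.0, 0.5, 1.5])
        rates = np.outer(weights, sig) + 1e-6 * rng.standard_normal((4, 3000))
        m = fit_factor_model(_rm(rates), 1)
        assert reconstruction_r2(m, _rm(rates)) > 0.999

    def test_r2_non_decreasing_in_k(self, rng):
        spec = LatentPopulationSpec(seed=3, duration=40.0, n_units=20)
        pop, _ = latent_population(spec)
        _, rm = standard_pipeline(pop)
        r2 = [reconstruction_r2(fit_factor_model(rm, k), rm) for k in range(1, 6)]
        assert all(b >= a - 1e-6 for a, b in zip(r2, r2[1:]))

    def test_white_noise_r2_small(self):
        worst = 0.0
        for seed in range(5):
            r = np.random.default_rng(seed)
            rm = _rm(r.standard_normal((20, 40 * 64)))
            worst = max(worst, reconstruction_r2(fit_factor_model(rm, 1), rm))
        assert worst < 0.2


class TestSurrogate:
    def _pop(self, seed=0, duration=30.0):
        pop, _ = latent_population(
            LatentPopulationSpec(k_true=1, mixing="homogeneous", seed=seed,
                                 duration=duration, n_units=15))
        return pop

    def test_spike_counts_and_span_preserved(self):
        pop = self._pop()
        sur = surrogate_population(pop, seed=42)
        for a, b in zip(pop.trains, sur.trains):
            assert a.n_spikes == b.n_spikes
            assert a.times[0] == b.times[0]
            assert np.isclose(a.times[-1], b.times[-1])

    def test_shuffling_destroys_common_drive(self):
        vals = []
        for seed in range(5):
            pop = self._pop(seed=seed)
            sur = surrogate_population(pop, seed=seed + 99)
            _, rm = standard_pipeline(sur)
            c = np.corrcoef(rm.rates)
            vals.append(np.abs(c[np.triu_indices_from(c, 1)]).mean())
        assert np.mean(vals) < 0.1


class TestSelection:
    def test_surrogate_against_itself_selects_one(self):
        # floor of the criterion: when the data curve IS the surrogate curve,
        # the fitted data slope cannot exceed the fitted surrogate slope
        pop = latent_population(
            LatentPopulationSpec(k_true=1, mixing="homogeneous", seed=5,
                                 duration=40.0, n_units=20))[0]
        sur = surrogate_population(pop, seed=1)
        spop, rm = standard_pipeline(sur)
        sel = DimensionalitySelector(kmax=6, seed=2, data_slope="fitted").fit(
            rm, spop, preprocess=lambda _: rm)
        assert sel.k_slope_ == 1

    def test_never_selects_kmax(self):
        pop = latent_population(
            LatentPopulationSpec(k_true=3, seed=6, duration=40.0, n_units=20))[0]
        spop, rm = standard_pipeline(pop)
        rep = select_dimensionality(rm, spop, kmax=4, seed=0)
        assert rep.k_slope <= 3

    def test_scale_invariance(self):
        pop = latent_population(
            LatentPopulationSpec(k_true=1, mixing="homogeneous", seed=7,
                                 duration=40.0, n_units=15))[0]
        spop, rm = standard_pipeline(pop)
        rep1 = select_dimensionality(rm, spop, kmax=5, seed=3)
        rm3 = SmoothedRateMatrix(3.0 * rm.rates, rm.fs, rm.unit_ids, detrended=True)

        def preprocess(sur):
            _, srm = standard_pipeline(sur)
            return SmoothedRateMatrix(3.0 * srm.rates, srm.fs, srm.unit_ids,
                                      detrended=True)

        sel = DimensionalitySelector(kmax=5, seed=3).fit(rm3, spop,
                                                         preprocess=preprocess)
        np.testing.assert_allclose(sel.r2_data_, rep1.r2_data, atol=1e-8)
        assert sel.k_slope_ == rep1.k_slope
        assert sel.k_5pct_ == rep1.k_5pct
        assert sel.k_mse_ == rep1.k_mse

    def test_report_curves_in_unit_interval(self):
        pop = latent_population(
            LatentPopulationSpec(k_true=1, mixing="homogeneous", seed=8,
                                 duration=40.0, n_units=15))[0]
        spop, rm = standard_pipeline(pop)
        rep = select_dimensionality(rm, spop, kmax=5, seed=4)
        for curve in (rep.r2_data, rep.r2_surrogate):
            assert np.all((curve >= 0) & (curve <= 1))
            assert np.all(np.diff(curve) >= -1e-6)


class _LoadingsOnly:
    """Minimal stand-in exposing the fields dominant_factor_clusters reads."""

    def __init__(self, loadings):
        self.loadings = np.asarray(loadings, float)
        self.unit_ids = tuple(f"u{i}" for i in range(self.loadings.shape[0]))


class TestDominantClusters:
    def test_argmax_and_tie_rule(self):
        m = _LoadingsOnly([[0.9, 0.1, -0.2],
                           [0.5, -0.5, 0.0],
                           [-0.1, 0.2, 0.8]])
        labels = dominant_factor_clusters(m)
        assert labels == {"u0": 0, "u1": 0, "u2": 2}

    def test_single_factor_single_cluster(self, rng):
        sig = lowpass_gaussian(2000, 64.0, 2.5, rng)[0]
        rates = np.outer([1, 2, 3.0], sig) + 0.05 * rng.standard_normal((3, 2000))
        m = fit_factor_model(_rm(rates), 1)
        assert set(dominant_factor_clusters(m).values()) == {0}
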