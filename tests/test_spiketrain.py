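"""Spike-train containers, smoothing, continuity, duplicates, thresholds."""

import numpy as np
import pytest

from muflex.spiketrain import (
    PopulationRecording,
    SpikeTrain,
    binarize,
    detrend_concat,
    filter_continuous,
    find_duplicates,
    read_spike_csv,
    recruitment_threshold,
    smooth_rates,
    write_spike_csv,
)
from muflex.synthetic import GAMMA_SHAPE

from conftest import regular_train


class TestContainers:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeTrain("u0", [0.5, 0.5, 1.0])

    def test_spike_beyond_duration_names_unit(self):
        with pytest.raises(ValueError, match="u7"):
            PopulationRecording((SpikeTrain("u7", [3.0]),), duration=2.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PopulationRecording((), duration=10.0, segments=[(0, 5), (4, 8)])

    def test_isi_cov_undefined_below_three_spikes(self):
        assert np.isnan(SpikeTrain("u0", [0.1, 0.5]).isi_cov())


class TestBinarize:
    def test_single_spike_lands_on_rounded_sample(self):
        vec = binarize(SpikeTrain("u0", [0.5]), fs=2048.0, duration=1.0)
        assert vec.size == 2048
        assert vec[1024] == 1.0 and vec.sum() == 1.0

    def test_empty_train_all_zero(self):
        assert binarize(SpikeTrain("u0", []), 2048.0, 1.0).sum() == 0.0

    def test_spike_count_conserved(self, rng):
        times = np.sort(rng.uniform(0, 9.9, size=57))
        times = np.unique(times)
        vec = binarize(SpikeTrain("u0", times), 2048.0, 10.0)
        assert vec.sum() == times.size


class TestSmoothing:
    def test_single_spike_bump_is_centered_and_symmetric(self):
        pop = PopulationRecording((SpikeTrain("u0", [1.0]),), duration=2.0, fs=1000.0)
        row = smooth_rates(pop).rates[0]
        center = int(round(1.0 * 1000))
        assert row[center] == row.max()
        half = 200  # kernel half-width in samples
        np.testing.assert_allclose(row[center - half:center],
                                   row[center + half:center:-1], atol=1e-9)

    def test_regular_train_interior_rate_near_nominal(self):
        pop = PopulationRecording((regular_train(10.0, 10.0),), duration=10.0,
                                  fs=2048.0)
        row = smooth_rates(pop).rates[0]
        interior = row[2048:-2048]
        assert abs(interior.mean() - 10.0) / 10.0 < 0.02

    def test_empty_train_zero_row(self):
        pop = PopulationRecording((SpikeTrain("u0", []),), duration=2.0, fs=512.0)
        assert np.all(smooth_rates(pop).rates == 0.0)

    def test_smoothing_conserves_spike_count(self):
        # spikes kept a kernel-length inside the edges (zero padding leaks
        # mass at the recording boundaries otherwise)
        trains = tuple(
            SpikeTrain(f"u{i}", np.arange(0.3, 9.7, 1.0 / r))
            for i, r in enumerate((8.0, 10.0, 12.0)))
        pop = PopulationRecording(trains, duration=10.0, fs=2048.0)
        rm = smooth_rates(pop)
        for i, tr in enumerate(pop.trains):
            integral = rm.rates[i].sum() / rm.fs
            assert abs(integral - tr.n_spikes) / tr.n_spikes < 0.005


class TestContinuityFilter:
    def _pop(self, *trains):
        return PopulationRecording(trains, duration=10.0, fs=2048.0)

    def test_unit_with_small_isis_retained(self):
        pop = self._pop(regular_train(3.0, 10.0, start=0.1))
        assert filter_continuous(pop, (0.0, 10.0)).n_units == 1

    def test_long_pause_removes_unit(self):
        t = np.concatenate([np.arange(0.1, 5.0, 0.1), np.arange(5.5, 9.95, 0.1)])
        pop = self._pop(SpikeTrain("gap", t))
        assert filter_continuous(pop, (0.0, 10.0)).n_units == 0

    def test_late_first_spike_removes_unit(self):
        pop = self._pop(regular_train(10.0, 10.0, start=0.6))
        assert filter_continuous(pop, (0.0, 10.0)).n_units == 0

    def test_idempotent(self, regular_pop):
        once = filter_continuous(regular_pop, (0.0, 10.0))
        twice = filter_continuous(once, (0.0, 10.0))
        assert once.unit_ids == twice.unit_ids

    def test_empty_result_warns(self):
        pop = self._pop(SpikeTrain("sparse", [1.0, 9.0]))
        with pytest.warns(UserWarning, match="removed every unit"):
            filter_continuous(pop, (0.0, 10.0))


class TestDetrendConcat:
    def test_exact_linear_trend_removed(self, regular_pop):
        rm = smooth_rates(regular_pop)
        t = np.arange(rm.n_samples) / rm.fs
        lin = np.vstack([2.0 + 0.5 * t, 7.0 - 0.2 * t, 1.0 + 0.0 * t])
        out = detrend_concat(type(rm)(lin, rm.fs, rm.unit_ids))
        np.testing.assert_allclose(out.rates, 0.0, atol=1e-9)

    def test_output_mean_and_slope_vanish(self, regular_pop):
        rm = detrend_concat(smooth_rates(regular_pop))
        t = np.arange(rm.n_samples) / rm.fs
        for row in rm.rates:
            assert abs(row.mean()) < 1e-9
            assert abs(np.polyfit(t, row, 1)[0]) < 1e-9

    def test_segment_concatenation_length(self, regular_pop):
        rm = smooth_rates(regular_pop)
        out = detrend_concat(rm, [(1.0, 4.0), (5.0, 8.0)])
        assert out.n_samples == int(6.0 * rm.fs)

    def test_affine_trend_invariance(self, regular_pop):
        rm = smooth_rates(regular_pop)
        base = detrend_concat(rm)
        t = np.arange(rm.n_samples) / rm.fs
        tilted = type(rm)(rm.rates + 3.0 + 0.7 * t, rm.fs, rm.unit_ids)
        np.testing.assert_allclose(detrend_concat(tilted).rates, base.rates,
                                   atol=1e-8)

    def test_segment_outside_matrix_errors(self, regular_pop):
        rm = smooth_rates(regular_pop)
        with pytest.raises(ValueError, match="segment"):
            detrend_concat(rm, [(8.0, 12.0)])


class TestDuplicates:
    def test_shifted_copy_is_duplicate(self, rng):
        base = np.cumsum(rng.gamma(GAMMA_SHAPE, 1 / (GAMMA_SHAPE * 10), 150))
        a = SpikeTrain("a", base)
        b = SpikeTrain("b", base + 0.002)
        groups, retained = find_duplicates([a, b])
        assert groups == [["a", "b"]]
        assert len(retained) == 1

    def test_independent_poisson_pairs_rarely_flagged(self):
        hits = 0
        n_pairs = 100
        for seed in range(n_pairs):
            r = np.random.default_rng(seed)
            a = SpikeTrain("a", np.unique(np.sort(r.uniform(0, 20, 200))))
            b = SpikeTrain("b", np.unique(np.sort(r.uniform(0, 20, 200))))
            groups, _ = find_duplicates([a, b])
            hits += bool(groups)
        assert hits <= 0.05 * n_pairs

    def test_lowest_isi_cov_retained(self, rng):
        # unit a: regular (low CoV); unit b: same times plus jitter (high CoV)
        base = np.arange(0.1, 20.0, 0.1)
        jit = np.sort(base + rng.uniform(-0.0004, 0.0004, base.size))
        a, b = SpikeTrain("a", base), SpikeTrain("b", jit)
        assert a.isi_cov() < b.isi_cov()
        _, retained = find_duplicates([a, b])
        assert retained == ["a"]

    def test_lag_invariance_of_grouping(self, rng):
        base = np.cumsum(rng.gamma(GAMMA_SHAPE, 1 / (GAMMA_SHAPE * 12), 200))
        other = np.unique(np.sort(rng.uniform(0, base[-1], 150)))
        for lag in (-0.010, -0.003, 0.0, 0.004, 0.010):
            trains = [SpikeTrain("a", base),
                      SpikeTrain("b", base + 1.0 + lag),  # copy, shifted
                      SpikeTrain("c", other + 1.0)]
            groups, _ = find_duplicates(
                [trains[0], SpikeTrain("b", trains[1].times - 1.0),
                 SpikeTrain("c", other)])
            assert groups == [["a", "b"]]


class TestRecruitmentThreshold:
    def test_linear_ramp_interpolation(self):
        fs = 100.0
        torque = np.linspace(0, 20, int(5 * fs) + 1)  # 0 -> 20 %MVC over 5 s
        train = SpikeTrain("u0", [1.0, 1.3, 1.6, 1.9])
        assert recruitment_threshold(train, torque, fs) == pytest.approx(4.0)

    def test_first_valid_triple_found_by_scan(self):
        fs = 100.0
        torque = np.linspace(0, 20, int(5 * fs) + 1)
        train = SpikeTrain("u0", [0.5, 2.0, 2.1, 2.2])
        # exhaustive-scan oracle over all triples
        t = train.times
        expected = next(t[i] for i in range(t.size - 2) if t[i + 2] - t[i] <= 1.0)
        assert expected == 2.0
        assert recruitment_threshold(train, torque, fs) == pytest.approx(8.0)

    def test_no_qualifying_triple_is_nan(self):
        fs = 100.0
        torque = np.linspace(0, 20, int(5 * fs) + 1)
        train = SpikeTrain("u0", [0.5, 1.6, 2.7])
        assert np.isnan(recruitment_threshold(train, torque, fs))


class TestCsvDialect:
    def test_round_trip(self, tmp_path, rng):
        trains = [
            SpikeTrain("mu01", np.sort(rng.uniform(0, 5, 40)), "grid1"),
            SpikeTrain("mu02", np.sort(rng.uniform(0, 5, 25)), "grid2"),
        ]
        path = tmp_path / "spikes.csv"
        write_spike_csv(trains, path)
        header = path.read_text().splitlines()[0]
        assert header == "unit_id,time_s,grid"
        back = read_spike_csv(path)
        assert [t.unit_id for t in back] == ["mu01", "mu02"]
        np.testing.assert_allclose(back[0].times, trains[0].times)
        assert back[1].source_grid == "grid2"
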