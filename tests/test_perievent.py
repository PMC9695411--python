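"""Kernel rate estimation, binning, correlations and modulation summaries."""

import numpy as np
import pytest

from pnhmicro import (
    AnnotationTable,
    UnitGainProfile,
    bin_rates,
    generate_unit_spikes,
    kernel_rate,
    modulation_percent,
    rate_lfp_correlation,
    seizure_raster,
)
from pnhmicro.cluster import Cluster, ClusterResult, cluster_permutation_test
from pnhmicro.perievent import baseline_bins
from pnhmicro.synth import sustained_gain


def _fake_result(up=(), down=(), n_bins=100):
    clusters = [Cluster(a, b, "up", 10.0, 0.001) for a, b in up]
    clusters += [Cluster(a, b, "down", -10.0, 0.001) for a, b in down]
    return ClusterResult(clusters, 0.01, 0.05, 1000, 0, np.zeros(n_bins))


class TestKernelRate:
    def test_single_spike_peak_is_gaussian_density(self):
        per = kernel_rate([10.0], [10.0], (-1.0, 1.0), sigma_s=0.010)
        peak = per.rate.max()
        assert peak == pytest.approx(1 / (0.010 * np.sqrt(2 * np.pi)), rel=0.01)
        assert abs(per.times[np.argmax(per.rate[0])]) <= 0.001

    def test_rate_integral_equals_spike_count(self, rng):
        spikes = np.sort(rng.uniform(9.0, 11.0, 37))
        spikes = spikes[(spikes > 9.2) & (spikes < 10.8)]  # keep 4 sigma off edges
        per = kernel_rate(spikes, [10.0], (-1.0, 1.0), sigma_s=0.050)
        integral = per.rate[0].sum() / 1000.0
        assert integral == pytest.approx(spikes.size, rel=0.01)

    def test_empty_train_gives_zero_rates(self):
        per = kernel_rate([], [10.0, 20.0], (-1.0, 1.0), sigma_s=0.010)
        assert per.rate.shape == (2, 2000)
        assert np.all(per.rate == 0)

    def test_gain_recovered_from_peak_to_baseline_ratio(self, make_annotations):
        onsets = np.arange(10.0, 1210.0, 12.0)
        ann = make_annotations([("SD+F", "m", o, o + 1.0) for o in onsets])
        prof = UnitGainProfile("u", 10.0, {"SD+F": sustained_gain(5.0, 1.0)})
        spikes = generate_unit_spikes(ann, prof, 1220.0, seed=8)
        per = kernel_rate(spikes, onsets, (-3.0, 3.0), sigma_s=0.050)
        avg = per.avg_rate
        plateau = (per.times >= 0.3) & (per.times <= 0.7)
        base = (per.times >= -2.0) & (per.times <= -1.0)
        ratio = avg[plateau].mean() / avg[base].mean()
        assert ratio == pytest.approx(5.0, rel=0.10)


class TestBinRates:
    def test_constant_rate_fills_all_bins(self):
        per = kernel_rate([], [0.0], (-1.0, 1.0), sigma_s=0.010)
        per.rate = np.full_like(per.rate, 10.0)
        binned = bin_rates(per)
        np.testing.assert_allclose(binned, 10.0)

    def test_bin_means_equal_direct_sums(self, rng):
        per = kernel_rate([], [0.0], (-1.0, 1.0), sigma_s=0.010)
        per.rate = rng.standard_normal(per.rate.shape)
        binned = bin_rates(per)
        w = per.rate.shape[1] // 100
        for b in range(100):
            direct = per.rate[0, b * w : (b + 1) * w].sum() / w
            assert binned[0, b] == pytest.approx(direct)

    def test_binned_total_conserves_integral(self, rng):
        per = kernel_rate([], [0.0], (-1.0, 1.0), sigma_s=0.010)
        per.rate = np.abs(rng.standard_normal(per.rate.shape))
        binned = bin_rates(per)
        bin_width = 2.0 / 100
        assert (binned.sum(axis=1) * bin_width) == pytest.approx(
            per.rate.sum(axis=1) / 1000.0
        )

    def test_indivisible_window_rejected(self):
        per = kernel_rate([], [0.0], (-1.0, 1.0), sigma_s=0.010)
        per.rate = per.rate[:, :1999]
        with pytest.raises(ValueError):
            bin_rates(per)


class TestRateLfpCorrelation:
    def test_affine_relation_is_perfect_correlation(self, rng):
        lfp = rng.standard_normal(500)
        rho, status = rate_lfp_correlation(3.0 * lfp + 7.0, lfp)
        assert status == "ok"
        assert rho == pytest.approx(1.0)

    def test_inverse_unit_negative(self, rng):
        lfp = np.exp(-((np.linspace(-2, 2, 1000)) ** 2))
        rate = 10.0 - 8.0 * lfp  # dips when the LFP deflects
        rho, _ = rate_lfp_correlation(rate, lfp)
        assert rho == pytest.approx(-1.0)

    def test_independent_noise_is_small(self, rng):
        n = 1000
        hits = 0
        for _ in range(40):
            rho, _ = rate_lfp_correlation(rng.standard_normal(n),
                                          rng.standard_normal(n))
            hits += abs(rho) < 3 / np.sqrt(n)
        assert hits >= 0.95 * 40 - 2

    def test_zero_variance_flagged(self):
        rho, status = rate_lfp_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(rho)
        assert "zero variance" in status


class TestModulationPercent:
    def _per(self, avg_profile):
        per = kernel_rate([], [0.0], (-3.0, 3.0), sigma_s=0.050)
        per.rate = np.tile(avg_profile, (6, 1))
        bin_rates(per)
        return per

    def test_triple_rate_reads_200_percent(self):
        profile = np.full(6000, 10.0)
        profile[3000:3600] = 30.0  # 3x baseline at bins 50-59
        per = self._per(profile)
        up, down = modulation_percent(
            per, _fake_result(up=[(50, 59)]), (-2.0, -1.0)
        )
        assert up == pytest.approx(200.0)
        assert down is None

    def test_silence_reads_100_percent_down(self):
        profile = np.full(6000, 10.0)
        profile[3000:3600] = 0.0
        per = self._per(profile)
        up, down = modulation_percent(
            per, _fake_result(down=[(50, 59)]), (-2.0, -1.0)
        )
        assert down == pytest.approx(100.0)
        assert up is None

    def test_no_clusters_is_ns_in_both_directions(self):
        per = self._per(np.full(6000, 10.0))
        up, down = modulation_percent(per, _fake_result(), (-2.0, -1.0))
        assert up is None and down is None

    def test_zero_baseline_rejected(self):
        per = self._per(np.zeros(6000))
        with pytest.raises(ValueError):
            modulation_percent(per, _fake_result(up=[(50, 51)]), (-2.0, -1.0))


class TestSeizureRaster:
    def test_row_per_seizure(self, rng):
        trains = {"u1": np.sort(rng.uniform(0, 4000, 20000))}
        onsets = np.linspace(200, 3800, 12)
        rasters = seizure_raster(trains, onsets, window_s=(-30.0, 30.0))
        assert len(rasters["u1"].trials) == 12

    def test_ictal_gain_ratio(self, make_annotations):
        onsets = np.arange(100.0, 1300.0, 100.0)
        ann = make_annotations(
            [("seizure", "m", o, o + 30.0) for o in onsets]
        )
        prof = UnitGainProfile("u", 10.0, {}, ictal_gain=3.0)
        spikes = generate_unit_spikes(ann, prof, 1350.0, seed=9)
        rasters = seizure_raster({"u": spikes}, onsets, window_s=(-30.0, 30.0))
        assert rasters["u"].ratio == pytest.approx(3.0, rel=0.2)
        # elevated in every single seizure
        for row in rasters["u"].trials:
            assert np.sum(row >= 0) > np.sum(row < 0)

    def test_empty_train_gives_empty_rows(self):
        rasters = seizure_raster({"u": np.array([])}, [100.0])
        assert all(r.size == 0 for r in rasters["u"].trials)

    def test_no_seizures_rejected(self):
        with pytest.raises(ValueError):
            seizure_raster({"u": np.arange(10.0)}, [])
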