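import numpy as np
import pytest
from scipy import stats

import tmrsim as tm


def make_epochs(x, n_epochs=3, rate=512.0, window=(-3.0, 3.0),
                labels=None):
    n = x.shape[-1]
    data = np.tile(x, (n_epochs, 1, 1)).reshape(n_epochs, 1, n)
    labels = (np.array(["sound"] * n_epochs) if labels is None
              else np.asarray(labels))
    return tm.EpochSet(data=data, rate=rate, window=window, labels=labels,
                       mask=np.ones(n_epochs, bool))


class TestEpochAndPreprocess:
    def test_window_arithmetic_and_edge_drop(self, nap30):
        events = [1.0, 30.0, 60.0, nap30.duration - 1.0]
        ep = tm.epoch_and_preprocess(nap30, events)
        assert ep.data.shape == (2, 1, 1536)  # 6 s at 256 Hz; 2 edge drops

    def test_no_usable_events_raises(self, nap30):
        with pytest.raises(tm.EmptyEpochsError):
            tm.epoch_and_preprocess(nap30, [0.5])

    def test_artifact_removed_only_when_both_stages_agree(self, nap30):
        events = [20.0 + 40 * k for k in range(20)]
        rec = tm.SyntheticRecording(nap30.data.copy(), nap30.rate,
                                    nap30.channel_labels, nap30.planted,
                                    nap30.hypnogram)
        i = int(events[7] * rec.rate)
        rec.data[0, i:i + 100] += 500.0
        ep = tm.epoch_and_preprocess(rec, events)
        assert not ep.mask[7]
        assert ep.mask.sum() == 19
        # large-but-not-outlier epochs (amplitude only) survive
        clean = tm.epoch_and_preprocess(nap30, events)
        assert clean.mask.all()

    def test_reference_hook_is_applied(self, nap30):
        ep = tm.epoch_and_preprocess(nap30, [30.0, 60.0],
                                     reference=lambda x: 2.0 * x)
        base = tm.epoch_and_preprocess(nap30, [30.0, 60.0])
        np.testing.assert_allclose(ep.data, 2.0 * base.data)


class TestTFRPercentChange:
    def test_frequency_grid_has_53_bins(self):
        assert tm.TFRConfig().freqs.size == 53

    def test_stationary_oscillation_has_flat_percent_change(self):
        rate = 512.0
        t = np.arange(int(6 * rate)) / rate - 3.0
        x = 10 * np.sin(2 * np.pi * 10.0 * t)
        tfr = tm.tfr_percent_change(make_epochs(x),
                                    tm.TFRConfig(resample_rate=rate))
        fi = np.argmin(np.abs(tfr.freqs - 10.0))
        sel = (tfr.times > -1.5) & (tfr.times < 1.5)
        assert np.nanmax(np.abs(tfr.data[:, :, fi, :][..., sel])) < 5.0

    def test_amplitude_doubling_reads_300_percent(self):
        rate = 512.0
        t = np.arange(int(6 * rate)) / rate - 3.0
        x = 10 * np.sin(2 * np.pi * 13.0 * (t + 3)) * (1 + (t > 0))
        tfr = tm.tfr_percent_change(make_epochs(x),
                                    tm.TFRConfig(resample_rate=rate))
        fi = np.argmin(np.abs(tfr.freqs - 13.0))
        sel = (tfr.times > 0.5) & (tfr.times < 2.5)
        post = np.nanmean(tfr.data[:, :, fi, :][..., sel])
        assert post == pytest.approx(300.0, rel=0.05)

    def test_baseline_bins_average_to_zero(self, nap30):
        ep = tm.epoch_and_preprocess(nap30, [30.0, 60.0, 90.0])
        cfg = tm.TFRConfig()
        tfr = tm.tfr_percent_change(ep, cfg)
        bsel = (tfr.times >= cfg.baseline[0] - 1e-9) & \
               (tfr.times <= cfg.baseline[1] + 1e-9)
        worst = np.nanmax(np.abs(np.nanmean(tfr.data[..., bsel], axis=-1)))
        assert worst < 1e-6

    def test_taper_edges_marked_invalid(self):
        rate = 512.0
        x = np.random.default_rng(0).standard_normal(int(6 * rate))
        tfr = tm.tfr_percent_change(make_epochs(x),
                                    tm.TFRConfig(resample_rate=rate))
        # at 4 Hz the 5-cycle taper spans 1.25 s; the first 0.6 s is invalid
        assert np.isnan(tfr.data[0, 0, 0, 0])
        mid = np.argmin(np.abs(tfr.times))
        assert not np.isnan(tfr.data[0, 0, 0, mid])

    def test_bad_baseline_rejected(self):
        x = np.zeros(int(6 * 512))
        with pytest.raises(ValueError):
            tm.tfr_percent_change(make_epochs(x),
                                  tm.TFRConfig(resample_rate=512.0,
                                               baseline=(-5.0, -4.0)))

    def test_sound_minus_sham_contrast_shape(self, nap30):
        ep = tm.epoch_and_preprocess(nap30, [30.0, 60.0, 90.0, 120.0],
                                     labels=["sound", "sham", "sound", "sham"])
        tfr = tm.tfr_percent_change(ep)
        diff = tm.sound_minus_sham(tfr, ep.clean_labels)
        assert diff.shape == (53, tfr.times.size)


class TestClusterPermutation:
    def test_sign_flip_symmetry(self, rng):
        X = rng.standard_normal((10, 20, 30)) + 0.4
        a = tm.cluster_permutation(X, n_perm=100, seed=1)
        b = tm.cluster_permutation(-X, n_perm=100, seed=1)
        sa = sorted((c.sign, c.size, round(c.p, 6)) for c in a.clusters)
        sb = sorted((-c.sign, c.size, round(c.p, 6)) for c in b.clusters)
        assert sa == sb

    def test_p_values_within_bounds(self, rng):
        X = rng.standard_normal((8, 15, 15)) + 0.8
        res = tm.cluster_permutation(X, n_perm=99, seed=2)
        for c in res.clusters:
            assert 1.0 / 100 <= c.p <= 1.0

    def test_matches_mne_cluster_formation(self, rng):
        """Observed clusters (bins and sizes) equal MNE's lattice clustering
        with cluster-size statistic (t_power=0) at the same threshold."""
        mne_stats = pytest.importorskip("mne.stats")
        X = rng.standard_normal((12, 20, 30)) + 0.3
        res = tm.cluster_permutation(X, alpha=0.01, n_perm=50, seed=3)
        tcrit = stats.t.ppf(1 - 0.005, 11)
        _, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            X, threshold=tcrit, tail=0, t_power=0, n_permutations=50,
            seed=4, out_type="mask", verbose=False)
        assert (sorted(c.size for c in res.clusters)
                == sorted(int(m.sum()) for m in clusters))

    def test_planted_effect_recovers_its_window(self, rng):
        """An effect confined to 4-7 Hz x 0.6-1.2 s produces a significant
        cluster covering >=80% of the planted bins."""
        cfg = tm.TFRConfig()
        times = np.arange(cfg.analysis_window[0],
                          cfg.analysis_window[1] + 1e-9, cfg.time_step)
        X = rng.standard_normal((20, 53, times.size))
        fsel = (cfg.freqs >= 4.0) & (cfg.freqs <= 7.0)
        tsel = (times >= 0.6) & (times <= 1.2)
        X[:, np.ix_(fsel, tsel)[0], np.ix_(fsel, tsel)[1]] += 1.0
        res = tm.cluster_permutation(X, n_perm=200, seed=5)
        sig = res.significant
        assert sig
        planted = {(f, t) for f in np.nonzero(fsel)[0]
                   for t in np.nonzero(tsel)[0]}
        covered = planted & set(sig[0].bins)
        assert len(covered) / len(planted) >= 0.8

    def test_null_familywise_rate_is_controlled(self, rng):
        """Under the null the probability of any significant cluster does not
        exceed the nominal level (the size statistic is conservative on
        spatially white maps)."""
        hits = 0
        runs = 40
        for _ in range(runs):
            X = rng.standard_normal((12, 25, 40))
            res = tm.cluster_permutation(X, n_perm=100,
                                         seed=int(rng.integers(2 ** 31)))
            hits += bool(res.significant)
        assert hits / runs <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / runs)

    def test_mass_statistic_option(self, rng):
        X = rng.standard_normal((10, 10, 10)) + 1.0
        res = tm.cluster_permutation(X, n_perm=50, seed=6, statistic="mass")
        assert res.clusters[0].stat > res.clusters[0].size  # mass sums |t|>2.8

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            tm.cluster_permutation(rng.standard_normal((1, 5, 5)))
        with pytest.raises(ValueError):
            tm.cluster_permutation(rng.standard_normal((5, 5, 5)), n_perm=0)
        bad = rng.standard_normal((5, 5, 5))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            tm.cluster_permutation(bad)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((8, 10, 10))
        a = tm.cluster_permutation(X, n_perm=100, seed=9)
        b = tm.cluster_permutation(X, n_perm=100, seed=9)
        assert np.array_equal(a.null_max, b.null_max)


class TestERP:
    def test_identical_epochs_reproduce_single_epoch(self):
        rate = 512.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(6 * rate))
        ep = make_epochs(x, n_epochs=4, rate=rate)
        out = tm.erp(ep, hp=0.0)
        t = ep.times
        bsel = (t >= -0.2) & (t <= 0.0)
        expected = x - x[bsel].mean()
        np.testing.assert_allclose(out[0], expected, atol=1e-9)

    def test_random_polarity_cancels(self):
        rate = 256.0
        rng = np.random.default_rng(2)
        x = np.sin(2 * np.pi * 2.0 * np.arange(int(6 * rate)) / rate)
        signs = np.array([1, -1] * 20)
        data = signs[:, None, None] * x[None, None, :]
        ep = tm.EpochSet(data=data, rate=rate, window=(-3, 3),
                         labels=np.array(["sound"] * 40),
                         mask=np.ones(40, bool))
        out = tm.erp(ep, hp=0.0)
        assert np.abs(out).max() < 1e-12

    def test_noise_averaging_scales_as_inverse_sqrt_n(self):
        rate = 256.0
        rng = np.random.default_rng(3)
        n = int(6 * rate)
        t = np.arange(n) / rate - 3.0
        common = 5.0 * np.exp(-((t - 0.5) ** 2) / 0.05)

        def err(n_trials):
            data = common + rng.standard_normal((n_trials, 1, n))
            ep = tm.EpochSet(data=data.reshape(n_trials, 1, n), rate=rate,
                             window=(-3, 3),
                             labels=np.array(["sound"] * n_trials),
                             mask=np.ones(n_trials, bool))
            out = tm.erp(ep, hp=0.0, baseline=(-3.0, -1.0))
            sel = (t > 1.5)
            return np.sqrt(np.mean((out[0] - (common - common[(t >= -3.0) & (t <= -1.0)].mean()))[sel] ** 2))

        e_small, e_big = err(8), err(128)
        assert e_big < e_small / 2.0  # expect ~1/4 at 16x trials
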