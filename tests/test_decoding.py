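"""Pseudo-trials, shrinkage LDA, CV AUC, forward models, clustering, peaks."""

import numpy as np
import pandas as pd
import pytest

from neurocmc.decoding import (PseudoTrialSet, SlidingWindowConfig,
                               bootstrap_threshold, build_pseudo_trials,
                               crossval_auc, decode_participant,
                               epoch_preprocess, extract_peak_amplitudes,
                               fit_window_lda, forward_model,
                               forward_model_series, realign_to_response,
                               temporal_clustering, window_average)
from neurocmc.synth import EpochSet


def _epochs(data, fs=200.0, t0=0.0):
    data = np.asarray(data, dtype=np.float32)
    times = np.arange(data.shape[2]) / fs + t0
    return EpochSet(data=data, sampling_rate=fs, times=times)


def _pset(data, labels, fs=200.0, t0=0.0, rts=None):
    data = np.asarray(data, dtype=np.float32)
    labels = np.asarray(labels)
    info = pd.DataFrame({"label": labels, "congruency": labels,
                         "rt": 0.5 if rts is None else rts})
    times = np.arange(data.shape[2]) / fs + t0
    return PseudoTrialSet(data=data, labels=labels, info=info, times=times,
                          sampling_rate=fs)


def _two_class_data(rng, n_per=30, n_ch=8, n_t=40, sep_channel=None, sep=2.0,
                    noise=1.0):
    X = noise * rng.standard_normal((2 * n_per, n_ch, n_t))
    labels = np.array(["incongruent"] * n_per + ["congruent"] * n_per)
    if sep_channel is not None:
        X[n_per:, sep_channel, :] += sep
        X[:n_per, sep_channel, :] -= sep
    return X, labels


class TestPseudoTrials:
    def _trials(self, n, congruency="congruent"):
        return pd.DataFrame({
            "participant_id": 0, "congruency": congruency,
            "modality": "auditory", "correct": True,
            "rt": np.linspace(0.4, 0.6, n)})

    def test_eight_trials_give_two_pseudo_trials(self, rng):
        tr = self._trials(8)
        ep = _epochs(rng.standard_normal((8, 4, 20)))
        ps = build_pseudo_trials(ep, tr, group_size=4, rng_seed=0)
        assert ps.n_pseudo == 2
        assert all(len(m) == 4 for m in ps.membership)

    def test_remainder_trials_discarded(self, rng):
        tr = self._trials(7)
        ep = _epochs(rng.standard_normal((7, 4, 20)))
        ps = build_pseudo_trials(ep, tr, group_size=4, rng_seed=0)
        assert ps.n_pseudo == 1

    def test_identical_sources_average_to_source(self, rng):
        one = rng.standard_normal((1, 4, 20)).astype(np.float32)
        ep = _epochs(np.repeat(one, 4, axis=0))
        ps = build_pseudo_trials(ep, self._trials(4), group_size=4, rng_seed=0)
        np.testing.assert_allclose(ps.data[0], one[0], rtol=1e-6)

    def test_no_source_trial_reused(self, rng):
        tr = pd.concat([self._trials(9, "congruent"),
                        self._trials(10, "incongruent")], ignore_index=True)
        ep = _epochs(rng.standard_normal((19, 4, 20)))
        ps = build_pseudo_trials(ep, tr, group_size=4, rng_seed=1)
        used = np.concatenate(ps.membership)
        assert len(used) == len(set(used))
        # cells keep their condition labels
        assert set(ps.info["label"]) == {"congruent", "incongruent"}

    def test_undersized_cell_warns(self, rng):
        tr = pd.concat([self._trials(4, "congruent"),
                        self._trials(3, "incongruent")], ignore_index=True)
        ep = _epochs(rng.standard_normal((7, 4, 20)))
        with pytest.warns(UserWarning, match="no pseudo-trials"):
            ps = build_pseudo_trials(ep, tr, group_size=4, rng_seed=0)
        assert ps.n_pseudo == 1

    def test_pseudo_rt_is_member_mean(self, rng):
        tr = self._trials(4)
        ep = _epochs(rng.standard_normal((4, 4, 20)))
        ps = build_pseudo_trials(ep, tr, group_size=4, rng_seed=0)
        assert ps.info["rt"].iloc[0] == pytest.approx(tr["rt"].mean())


class TestWindowLDA:
    def test_informative_channel_recovered(self, rng):
        """Two classes separated along one channel, negligible noise: the
        normalized filter concentrates on that channel."""
        X, labels = _two_class_data(rng, sep_channel=3, sep=3.0, noise=1e-3)
        ps = _pset(X, labels)
        w, proj = fit_window_lda(ps, (0.0, 0.2))
        wn = w / np.linalg.norm(w)
        e3 = np.zeros(8)
        e3[3] = 1.0
        assert abs(wn @ e3) >= 0.99
        assert proj[labels == "congruent"].mean() > 0

    def test_no_signal_gives_chance_auc(self, rng):
        X, labels = _two_class_data(rng, sep_channel=None)
        ps = _pset(X, labels)
        auc, _ = crossval_auc(ps, SlidingWindowConfig(0.06, 0.02), rng_seed=0)
        assert abs(auc.mean() - 0.5) < 0.1

    def test_closed_form_two_channel_solution(self, rng):
        """Unregularized filter equals pooled-covariance solve computed
        independently with numpy on the same window."""
        X, labels = _two_class_data(rng, n_per=100, n_ch=2, n_t=10, noise=1.0)
        X[labels == "congruent", 0] += 1.0
        X[labels == "congruent", 1] += 0.5
        ps = _pset(X, labels)
        w, _ = fit_window_lda(ps, (0.0, 0.05), shrinkage=0.0)
        Xm = np.asarray(X[:, :, :10], float).mean(axis=2)
        y = (labels == "congruent")
        mu1, mu0 = Xm[y].mean(0), Xm[~y].mean(0)
        pooled = (np.cov(Xm[y].T, bias=True) * y.sum()
                  + np.cov(Xm[~y].T, bias=True) * (~y).sum()) / len(y)
        expected = np.linalg.solve(pooled, mu1 - mu0)
        cos = w @ expected / np.linalg.norm(w) / np.linalg.norm(expected)
        assert cos > 0.999

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4, 20))
        ps = _pset(X, np.array(["congruent"] * 10))
        with pytest.raises(ValueError, match="two classes"):
            fit_window_lda(ps, (0.0, 0.05))

    def test_sign_convention_congruent_mean_nonnegative(self, rng):
        """Whatever the channel polarity, the congruent-class mean
        projection is oriented non-negative."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, labels = _two_class_data(r, sep_channel=2, sep=-2.0, noise=0.5)
            ps = _pset(X, labels)
            res = decode_participant(ps, SlidingWindowConfig(0.06, 0.02),
                                     n_splits=3, rng_seed=0)
            cong = res.projections[labels == "congruent"]
            assert (cong.mean(axis=0) >= -1e-9).all()


class TestCrossvalAUC:
    def test_separable_signal_saturates_auc(self, rng):
        X, labels = _two_class_data(rng, sep_channel=1, sep=5.0, noise=0.1)
        ps = _pset(X, labels)
        auc, onsets = crossval_auc(ps, SlidingWindowConfig(0.06, 0.02),
                                   rng_seed=0)
        assert auc.min() > 0.99
        assert onsets[0] == pytest.approx(0.0)

    def test_permuted_labels_chance_level(self, rng):
        """Averaged over label permutations the CV AUC is at chance.  (A
        single fixed permutation retains dataset-level spurious separation
        shared between train and test folds, which is exactly what the
        max-statistic randomization threshold accounts for.)"""
        X, labels = _two_class_data(rng, sep_channel=1, sep=3.0, noise=0.5)
        ps = _pset(X, labels)
        aucs = []
        for seed in range(12):
            perm = rng.permutation(labels)
            auc, _ = crossval_auc(ps, SlidingWindowConfig(0.06, 0.02),
                                  labels=perm, rng_seed=seed)
            aucs.append(auc.mean())
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < max(3 * se, 0.03)

    def test_duplicated_dataset_invariance(self, rng):
        X, labels = _two_class_data(rng, sep_channel=1, sep=1.0, noise=1.0)
        ps = _pset(X, labels)
        ps2 = _pset(np.concatenate([X, X]), np.concatenate([labels, labels]))
        cfg = SlidingWindowConfig(0.06, 0.02)
        auc1, _ = crossval_auc(ps, cfg, rng_seed=0)
        auc2, _ = crossval_auc(ps2, cfg, rng_seed=0)
        assert abs(auc1.mean() - auc2.mean()) < 0.08

    def test_pseudo_trial_averaging_boosts_auc(self, rng):
        """Averaging 4 same-condition trials raises the window AUC on a
        planted weak signal (signal-to-noise gain)."""
        n, ch, t = 96, 6, 30
        X = rng.standard_normal((n, ch, t))
        labels = np.array(["incongruent", "congruent"] * (n // 2))
        X[labels == "congruent", 0] += 0.7
        X[labels == "incongruent", 0] -= 0.7
        trials = pd.DataFrame({"participant_id": 0, "congruency": labels,
                               "modality": "auditory", "correct": True,
                               "rt": 0.5})
        ep = _epochs(X)
        cfg = SlidingWindowConfig(0.06, 0.02)
        means = {}
        for gs in (1, 4):
            ps = build_pseudo_trials(ep, trials, group_size=gs, rng_seed=0)
            auc, _ = crossval_auc(ps, cfg, rng_seed=0)
            means[gs] = auc.mean()
        assert means[4] > means[1]


class TestBootstrapThreshold:
    def test_threshold_exceeds_chance(self, rng):
        X, labels = _two_class_data(rng, n_per=16, n_ch=4, n_t=30)
        psets = [_pset(X, labels)]
        with pytest.warns(UserWarning, match="unstable"):
            thr = bootstrap_threshold(psets, SlidingWindowConfig(0.06, 0.02),
                                      n_randomizations=40, rng_seed=0)
        assert thr > 0.5

    def test_doubling_randomizations_stable(self, rng):
        X, labels = _two_class_data(rng, n_per=16, n_ch=4, n_t=30)
        psets = [_pset(X, labels)]
        cfg = SlidingWindowConfig(0.06, 0.02)
        t1 = bootstrap_threshold(psets, cfg, n_randomizations=150,
                                 percentile=95, rng_seed=0)
        t2 = bootstrap_threshold(psets, cfg, n_randomizations=300,
                                 percentile=95, rng_seed=1)
        assert abs(t1 - t2) < 0.05


class TestForwardModel:
    def test_rank_one_identity(self, rng):
        a0 = rng.standard_normal(6)
        y = rng.standard_normal(50)
        X = np.outer(y, a0)
        a = forward_model(y, X)
        cos = a @ a0 / np.linalg.norm(a0)
        assert abs(cos) == pytest.approx(1.0, abs=1e-10)

    def test_planted_pattern_recovered_at_snr_one(self, rng):
        a0 = rng.standard_normal(16)
        a0 /= np.linalg.norm(a0)
        y = rng.standard_normal(300)
        X = np.outer(y, a0) + 1.0 * rng.standard_normal((300, 16)) / 4
        a = forward_model(y, X)
        assert abs(a @ a0) >= 0.9

    def test_orthogonal_projection_flagged(self, rng):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.ones((4, 5))                      # channels constant: X^T y = 0
        with pytest.warns(UserWarning, match="orthogonal"):
            a = forward_model(y, X)
        assert np.allclose(a, 0)

    def test_zero_variance_projection_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            forward_model(np.zeros(4), np.ones((4, 3)))


class TestTemporalClustering:
    def test_two_alternating_patterns(self, rng):
        p1 = np.zeros(8); p1[0] = 1.0
        p2 = np.zeros(8); p2[4] = 1.0
        topos = np.array([p1, p2] * 10) + 0.01 * rng.standard_normal((20, 8))
        sol = temporal_clustering(topos, np.arange(20) * 0.005, rng_seed=0)
        assert sol.k == 2

    def test_identical_topographies_collapse_to_one(self):
        topos = np.tile(np.ones(6) / np.sqrt(6), (10, 1))
        sol = temporal_clustering(topos, np.arange(10) * 0.005, rng_seed=0)
        assert sol.k == 1 and np.isnan(sol.silhouette)

    def test_three_sequential_patterns(self, rng):
        """Three orthogonal patterns in consecutive time ranges: the
        silhouette criterion selects k = 3."""
        pats = np.eye(9)[:3]
        topos = np.concatenate([np.tile(p, (8, 1)) for p in pats])
        topos += 0.02 * rng.standard_normal(topos.shape)
        onsets = np.arange(24) * 0.005
        sol = temporal_clustering(topos, onsets, rng_seed=0)
        assert sol.k == 3
        starts = sorted(r[1] for r in sol.time_ranges)
        assert starts == pytest.approx([0.0, 0.04, 0.08])


class TestPeakAmplitudes:
    def _result(self):
        from neurocmc.decoding import DecodingResult
        onsets = np.arange(0.0, 0.61, 0.05)
        auc = np.full(onsets.size, 0.5)
        auc[np.argmin(abs(onsets - 0.20))] = 0.9     # early peak
        auc[np.argmin(abs(onsets - 0.50))] = 0.8     # late peak
        proj = np.tile(np.linspace(-2, 2, 4)[:, None], (1, onsets.size))
        info = pd.DataFrame({"congruency": ["congruent", "congruent",
                                            "incongruent", "incongruent"],
                             "rt": 0.5})
        return DecodingResult(onsets=onsets, filters=np.zeros((onsets.size, 3)),
                              projections=proj, auc=auc, info=info)

    def test_peak_latency_is_argmax_in_range(self):
        res = self._result()
        out = extract_peak_amplitudes(res, (0.125, 0.30), (0.40, 0.60))
        assert out["early_peak_latency"].iloc[0] == pytest.approx(0.20)
        assert out["late_peak_latency"].iloc[0] == pytest.approx(0.50)

    def test_congruency_normalization_flips_incongruent_sign(self):
        res = self._result()
        out = extract_peak_amplitudes(res, (0.125, 0.30), (0.40, 0.60))
        np.testing.assert_allclose(out["y_early_max"],
                                   [-2.0, -2 / 3, -2 / 3, -2.0])

    def test_search_window_outside_range_rejected(self):
        res = self._result()
        with pytest.raises(ValueError, match="outside decoded"):
            extract_peak_amplitudes(res, (0.8, 0.9), (0.4, 0.6))


class TestRealignment:
    def test_zero_rt_is_identity_restriction(self, rng):
        X = rng.standard_normal((5, 3, 100)).astype(np.float32)
        ep = EpochSet(data=X, sampling_rate=200.0,
                      times=np.arange(100) / 200.0 - 0.3)
        tr = pd.DataFrame({"rt": np.zeros(5)})
        out = realign_to_response(ep, tr, window=(-0.2, 0.1))
        sel = (ep.times >= -0.2 - 1e-9) & (ep.times < 0.1 - 1e-9)
        np.testing.assert_allclose(out.data, X[:, :, sel])
        assert out.alignment == "response"

    def test_rt_maps_stimulus_time_to_response_zero(self, rng):
        X = rng.standard_normal((1, 2, 200)).astype(np.float32)
        ep = EpochSet(data=X, sampling_rate=200.0,
                      times=np.arange(200) / 200.0 - 0.3)
        tr = pd.DataFrame({"rt": [0.2]})
        out = realign_to_response(ep, tr, window=(-0.1, 0.1))
        j0 = np.argmin(np.abs(out.times))
        src = np.argmin(np.abs(ep.times - 0.2))
        assert out.data[0, 0, j0] == X[0, 0, src]

    def test_out_of_range_trials_dropped_with_warning(self, rng):
        X = rng.standard_normal((3, 2, 100)).astype(np.float32)
        ep = EpochSet(data=X, sampling_rate=200.0,
                      times=np.arange(100) / 200.0 - 0.3)
        tr = pd.DataFrame({"rt": [0.1, 5.0, 0.15]})
        with pytest.warns(UserWarning, match="dropping"):
            out = realign_to_response(ep, tr, window=(-0.1, 0.05))
        assert out.data.shape[0] == 2

    def test_response_locked_component_only_decodable_after_realignment(self, rng):
        """A component tied to the response time is smeared stimulus-locked
        but cleanly decodable once epochs are response-aligned."""
        n, ch = 120, 6
        fs = 200.0
        times = np.arange(240) / fs - 0.3
        rts = rng.uniform(0.3, 0.7, n)
        labels = np.array(["congruent", "incongruent"] * (n // 2))
        sign = np.where(labels == "congruent", 1.0, -1.0)
        pat = np.zeros(ch); pat[2] = 1.0
        X = 0.8 * rng.standard_normal((n, ch, times.size))
        for i in range(n):
            env = np.exp(-0.5 * ((times - (rts[i] - 0.05)) / 0.02) ** 2)
            X[i] += sign[i] * 2.0 * np.outer(pat, env)
        ep = EpochSet(data=X.astype(np.float32), sampling_rate=fs, times=times)
        tr = pd.DataFrame({"rt": rts, "congruency": labels})
        cfg = SlidingWindowConfig(0.06, 0.02)
        stim = _pset(X, labels, t0=-0.3)
        auc_stim, on_s = crossval_auc(stim, cfg, rng_seed=0)
        re = realign_to_response(ep, tr, window=(-0.2, 0.05))
        resp = _pset(re.data, labels, t0=-0.2)
        auc_resp, on_r = crossval_auc(resp, cfg, rng_seed=0)
        assert auc_resp.max() > 0.95
        assert auc_resp.max() > auc_stim.max() + 0.05


class TestPreprocess:
    def test_constant_offset_removed_by_baseline(self):
        data = np.full((2, 3, 200), 7.0, dtype=np.float32)
        ep = EpochSet(data=data, sampling_rate=200.0,
                      times=np.arange(200) / 200.0 - 0.3)
        out = epoch_preprocess(ep, lowpass_hz=None, baseline=(-0.3, 0.0))
        assert np.abs(out.data).max() < 1e-6

    def test_50hz_attenuated_by_30hz_lowpass(self):
        fs = 200.0
        times = np.arange(400) / fs - 0.3
        tone = np.sin(2 * np.pi * 50.0 * times)
        data = np.tile(tone, (1, 1, 1)).astype(np.float32)
        ep = EpochSet(data=data, sampling_rate=fs, times=times)
        out = epoch_preprocess(ep, lowpass_hz=30.0, baseline=None)
        mid = slice(100, 300)                    # avoid filter edge effects
        atten = np.std(out.data[0, 0, mid]) / np.std(data[0, 0, mid])
        assert 20 * np.log10(atten) < -20.0

    def test_baseline_noise_floor_scaling(self, rng):
        """On DC-free white noise the baseline correction shifts values by
        O(1/sqrt(n_baseline_samples))."""
        fs = 200.0
        n_base = 60
        data = rng.standard_normal((200, 1, 200)).astype(np.float32)
        ep = EpochSet(data=data, sampling_rate=fs,
                      times=np.arange(200) / fs - n_base / fs)
        out = epoch_preprocess(ep, lowpass_hz=None, baseline=(-n_base / fs, 0.0))
        shifts = (data - out.data)[:, 0, 0]
        assert shifts.std() == pytest.approx(1 / np.sqrt(n_base), rel=0.25)

    def test_cutoff_above_nyquist_rejected(self):
        ep = EpochSet(data=np.zeros((1, 1, 50), dtype=np.float32),
                      sampling_rate=100.0, times=np.arange(50) / 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            epoch_preprocess(ep, lowpass_hz=60.0, baseline=None)


class TestWindowAverage:
    def test_window_mean_against_direct_computation(self, rng):
        data = rng.standard_normal((3, 2, 50))
        times = np.arange(50) / 100.0
        cfg = SlidingWindowConfig(window_length=0.05, step=0.02)
        out, onsets = window_average(data, times, cfg)
        # first window covers samples 0..4
        np.testing.assert_allclose(out[..., 0], data[..., :5].mean(-1),
                                   rtol=1e-5)
        assert onsets[1] - onsets[0] == pytest.approx(0.02)


class TestAmplitudeRecovery:
    """Consistency of the peak-amplitude estimator.

    The signed discriminant projection tracks the planted signed amplitude;
    the correlation is strong at the default noise level and approaches 1
    as noise vanishes.  (It cannot reach 1 at finite noise: the projection
    noise exceeds the within-class amplitude spread whenever AUC < 1, and
    the discriminant down-weights the amplitude-variation direction, which
    is within-class variance.)
    """

    def _signed_rho(self, noise_sd):
        from scipy.stats import spearmanr
        from neurocmc.synth import default_ground_truth, synthesize_dataset
        truth = default_ground_truth(n_channels=32, rng_seed=5)
        truth.noise_sd = noise_sd
        trials, epochs, _ = synthesize_dataset(n_participants=1, n_channels=32,
                                               rng_seed=3, truth=truth)
        pre = epoch_preprocess(epochs)
        pset = build_pseudo_trials(pre, trials, rng_seed=0)
        res = decode_participant(pset, SlidingWindowConfig(), rng_seed=0)
        tr = trials.reset_index(drop=True)
        planted = np.array([tr.iloc[m]["y_early"].mean()
                            for m in pset.membership])
        sign = np.where(pset.info["congruency"] == "congruent", 1.0, -1.0)
        j = np.argmin(np.abs(res.onsets - 0.19))
        return spearmanr(res.projections[:, j], sign * planted).statistic

    def test_signed_amplitude_tracking(self):
        rho_default = self._signed_rho(2.5)
        rho_clean = self._signed_rho(0.2)
        assert rho_default > 0.5
        assert rho_clean > 0.9
        assert rho_clean > rho_default


class TestStimulusFeatureDecoding:
    def test_same_operations_decode_stimulus_features(self, rng):
        """Feature decoding (e.g. high vs. low pitch) reuses the congruency
        machinery via the label column; a planted feature-locked pattern is
        found regardless of the congruency labels."""
        n, ch, t = 64, 6, 40
        X = rng.standard_normal((n, ch, t)).astype(np.float32)
        feats = np.array(["high_pitch", "low_pitch"] * (n // 2))
        X[feats == "high_pitch", 4] += 1.5
        trials = pd.DataFrame({
            "participant_id": 0,
            "congruency": rng.permutation(["congruent", "incongruent"] * (n // 2)),
            "modality": "auditory", "correct": True,
            "stimulus_feature": feats, "rt": 0.5})
        ep = _epochs(X)
        ps = build_pseudo_trials(ep, trials, group_size=2, rng_seed=0,
                                 label_column="stimulus_feature",
                                 condition_keys=("stimulus_feature", "correct"))
        assert set(ps.labels) == {"high_pitch", "low_pitch"}
        auc, _ = crossval_auc(ps, SlidingWindowConfig(0.06, 0.02), rng_seed=0)
        assert auc.max() > 0.9
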