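"""Generator contracts: point process statistics, rendering, noise,
behavioral protocol and ground-truth consistency."""

import numpy as np
import pytest

from muhit.features import select_trials
from muhit.io import BehavioralLog
from muhit.synth import (SessionConfig, add_noise, generate_behavior,
                         generate_session, generate_spike_train,
                         make_template, render_signal)

FS = 24414.0


class TestSpikeTrain:
    def test_zero_rate_gives_no_spikes(self):
        assert len(generate_spike_train(np.zeros(10_000), 1000.0)) == 0

    def test_poisson_count_calibration(self):
        """rate 20 Hz over 100 s: mean count 2000, so the seed-averaged
        count must sit within 3 standard errors of it."""
        rate = np.full(100_000, 20.0)
        counts = [len(generate_spike_train(rate, 1000.0, seed=s))
                  for s in range(20)]
        se = np.sqrt(2000.0 / 20)
        assert np.mean(counts) == pytest.approx(2000.0, abs=3 * se)

    def test_refractory_caps_rate(self):
        rate = np.full(10_000, 1000.0)      # 10 s at 1 kHz demand
        t = generate_spike_train(rate, 1000.0, refractory_s=0.002, seed=3)
        assert len(t) / 10.0 <= 500.0
        assert np.all(np.diff(t) >= 0.002)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_spike_train(np.array([-1.0, 5.0]), 1000.0)

    def test_deterministic_given_seed(self):
        rate = np.full(5000, 30.0)
        a = generate_spike_train(rate, 1000.0, seed=11)
        b = generate_spike_train(rate, 1000.0, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_inhomogeneous_rate_followed(self):
        """Twice the rate in the second half gives ~twice the spikes."""
        rate = np.concatenate([np.full(50_000, 10.0), np.full(50_000, 30.0)])
        t = generate_spike_train(rate, 1000.0, seed=5)
        n1 = np.sum(t < 50.0)
        n2 = np.sum(t >= 50.0)
        assert n2 / n1 == pytest.approx(3.0, rel=0.2)


class TestRenderSignal:
    def test_single_spike_peak_placement(self):
        template = make_template(FS, amplitude_v=50e-6)
        x = render_signal([1.0], template, 2.0, FS)
        assert x.min() == pytest.approx(-50e-6, rel=1e-6)
        peak = int(round(1.0 * FS)) + int(np.argmin(template))
        assert np.argmin(x) == peak
        assert np.count_nonzero(x) == np.count_nonzero(template)

    def test_empty_spike_list(self):
        x = render_signal([], np.array([1.0, -1.0]), 1.0, FS)
        assert np.all(x == 0)

    def test_linearity_of_overlap(self):
        template = make_template(FS, amplitude_v=1.0)
        t1, t2 = 0.5, 0.5 + 0.2e-3
        x12 = render_signal([t1, t2], template, 1.0, FS)
        x1 = render_signal([t1], template, 1.0, FS)
        x2 = render_signal([t2], template, 1.0, FS)
        np.testing.assert_allclose(x12, x1 + x2, atol=1e-15)

    def test_spike_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            render_signal([1.5], np.array([1.0]), 1.0, FS)


class TestTemplate:
    def test_biphasic_negative_leading(self):
        t = make_template(FS, amplitude_v=40e-6)
        assert np.max(np.abs(t)) == pytest.approx(40e-6)
        assert np.argmin(t) < np.argmax(t)       # negative lobe first
        assert 0.5e-3 < len(t) / FS < 2.5e-3     # about a millisecond


class TestAddNoise:
    def test_zero_sigma_identity(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(add_noise(x, "white", 0.0, seed=1), x)

    def test_white_sd_calibration(self):
        out = add_noise(np.zeros(244_140), "white", 5e-6, seed=2)
        assert out.std() == pytest.approx(5e-6, rel=0.02)

    def test_pink_mixture_sd(self):
        out = add_noise(np.zeros(244_140), "white+pink", 5e-6, seed=3)
        assert out.std() == pytest.approx(5e-6, rel=0.05)

    def test_artifact_bursts_are_louder(self):
        out, info = add_noise(np.zeros(int(30 * FS)),
                              "white+artifact_bursts", 1.0, seed=4, fs=FS,
                              return_info=True)
        assert info["burst_intervals"], "expected at least one burst in 30 s"
        mask = np.zeros(len(out), dtype=bool)
        for t0, t1 in info["burst_intervals"]:
            mask[int(t0 * FS):int(t1 * FS)] = True
        assert out[mask].std() > 2.0 * out[~mask].std()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="noise model"):
            add_noise(np.zeros(10), "brown", 1.0)


class TestBehavior:
    def test_three_hits_per_trial(self):
        log = generate_behavior(SessionConfig(n_trials=10, seed=1))
        hits = log.hits()
        assert len(hits) == 30
        assert hits.groupby("trial_id").size().eq(3).all()

    def test_all_accepted_when_no_failures(self):
        cfg = SessionConfig(n_trials=10, failure_fraction=0.0,
                            short_pair_fraction=0.0, seed=2)
        log = generate_behavior(cfg)
        assert log.events["accepted_flag"].all()
        assert len(select_trials(log)) == 10

    def test_retraction_gap_at_least_9s(self):
        log = generate_behavior(SessionConfig(n_trials=8, seed=3))
        hits = log.hits().groupby("trial_id")["time_s"]
        last = hits.max().to_numpy()
        first = hits.min().to_numpy()
        assert np.all(first[1:] - last[:-1] >= 9.0)

    def test_failure_trials_flagged_with_reason(self):
        cfg = SessionConfig(n_trials=40, failure_fraction=0.5, seed=4)
        log = generate_behavior(cfg)
        ev = log.events
        failed = ev[~ev["accepted_flag"]]
        assert len(failed) > 0
        assert (failed["failure_reason"]
                .isin(["non_preferred_limb", "premature_hit"]).all())
        assert failed["trial_id"].nunique() not in (0, 40)

    def test_short_pairs_generated_for_exclusion(self):
        cfg = SessionConfig(n_trials=40, failure_fraction=0.0,
                            short_pair_fraction=1.0, seed=5)
        log = generate_behavior(cfg)
        gaps = (log.hits().groupby("trial_id")["time_s"]
                .apply(lambda s: np.diff(np.sort(s)).min()))
        assert (gaps < 0.2).all()
        assert len(select_trials(log)) == 0

    def test_infeasible_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_behavior(SessionConfig(n_trials=10, duration_s=5.0))


class TestGenerateSession:
    def test_determinism(self):
        cfg = SessionConfig(n_trials=3, n_channels=2,
                            channel_categories=("paw", "none"), seed=99)
        s1, l1, t1 = generate_session(cfg)
        s2, l2, t2 = generate_session(cfg)
        np.testing.assert_array_equal(s1.signals, s2.signals)
        assert l1.events.equals(l2.events)
        for a, b in zip(t1.spike_times, t2.spike_times):
            np.testing.assert_array_equal(a, b)

    def test_ground_truth_refractory_and_sorted(self, small_session):
        _, _, truth = small_session
        for t in truth.spike_times:
            assert np.all(np.diff(t) >= 0.001 - 1e-9)

    def test_rate_fidelity(self, small_session):
        """Realized counts match the integral of the ground-truth rate
        profile to within 3 Monte-Carlo sigma."""
        session, _, truth = small_session
        for ch in range(session.n_channels):
            expected = truth.expected_count(ch, 0.0, session.duration_s)
            observed = len(truth.spike_times[ch])
            assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_prehit_rate_elevation_on_paw_channels(self, small_session):
        session, log, truth = small_session
        hits = sorted(select_trials(log).values())
        pre = sum(truth.expected_count(0, t - 0.3, t) for t in hits)
        base = sum(truth.expected_count(0, t - 0.9, t - 0.6) for t in hits)
        cfg_mod = 3.0
        assert pre / base == pytest.approx(cfg_mod, rel=1e-6)
        # non-movement channel is unmodulated
        pre1 = sum(truth.expected_count(1, t - 0.3, t) for t in hits)
        base1 = sum(truth.expected_count(1, t - 0.9, t - 0.6) for t in hits)
        assert pre1 == pytest.approx(base1, rel=1e-9)

    def test_rendered_spikes_match_ground_truth(self):
        """Every ground-truth spike leaves its waveform in the noiseless
        signal: regenerate with zero noise and check peak alignment."""
        cfg = SessionConfig(n_trials=2, n_channels=1,
                            channel_categories=("paw",), noise_sigma_v=0.0,
                            amplitude_jitter=0.0, seed=5)
        session, _, truth = cfg, None, None
        session, log, truth = generate_session(cfg)
        x = session.signals[0].astype(float)
        t_spk = truth.spike_times[0]
        assert len(t_spk) > 10
        peak_off = int(np.argmin(truth.template))
        idx = np.round(t_spk * cfg.fs).astype(int) + peak_off
        idx = idx[idx < len(x)]
        assert np.all(x[idx] < -0.2 * truth.template_peak_v)

    def test_null_config_has_flat_rates(self):
        cfg = SessionConfig.null(seed=1, n_trials=2)
        _, _, truth = generate_session(cfg)
        assert np.all(truth.rate_profiles == truth.rate_profiles[0, 0])
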