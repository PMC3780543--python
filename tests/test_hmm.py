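"""Two-state HMM burst calling, dwell extraction, dwell-time estimation."""

import numpy as np
import pytest

from burstkit import (
    DwellSet,
    IntensityTrace,
    TelegraphParams,
    TraceHMM,
    TraceSimConfig,
    estimate_switching_rates,
    extract_dwells,
    fit_dwell_exponential,
    fit_hmm_decode,
    simulate_traces,
)


def _trace(values, dt=15.0):
    values = np.asarray(values, float)
    return IntensityTrace(trace_id=0, times=np.arange(len(values)) * dt, intensity=values)


class TestDecoding:
    def test_noiseless_square_wave_decoded_exactly(self):
        states = np.array([0, 0, 1, 1, 1, 0, 1, 1, 0, 0, 0, 1, 1, 0, 1, 1])
        trace = _trace(states * 10.0)
        _, path, post = fit_hmm_decode(trace, seed=0)
        assert np.array_equal(path, states)
        assert np.all(post.argmax(axis=1) == states)

    def test_on_state_is_higher_emission_mean(self):
        rng = np.random.default_rng(0)
        states = (np.arange(60) // 5) % 2
        trace = _trace(states * 8.0 + rng.normal(0, 0.5, 60))
        est, path, _ = fit_hmm_decode(trace, seed=0)
        assert est.means_[1] > est.means_[0]
        assert np.mean(path == states) > 0.95

    def test_constant_trace_is_single_state_all_off(self):
        est, path, post = fit_hmm_decode(_trace(np.full(30, 2.0)), seed=0)
        assert est.single_state_
        assert np.all(path == 0)
        assert np.all(post[:, 0] == 1.0)

    def test_noise_only_trace_has_near_zero_occupancy(self):
        """A vehicle-control trace (no activity, only noise) decodes all-off."""
        rng = np.random.default_rng(3)
        est, path, _ = fit_hmm_decode(_trace(rng.normal(0.0, 1.0, 60)), seed=0)
        assert path.mean() <= 0.05

    def test_decoding_accuracy_against_simulator_truth(self):
        """Frame misclassification < 5% at SNR 5 on 200 synthetic traces.

        Kinetics (90-min mean dwells at 15-min frames) are chosen so the
        state sequence is actually identifiable from the sampled intensity.
        """
        params = TelegraphParams(1 / 90, 1 / 90, 2.0, 0.0)
        cfg = TraceSimConfig(15, 900, 5.0, 2.0, "steady")
        sims = simulate_traces(params, cfg, 200, 11)
        est = TraceHMM(normalize="global", random_state=0).fit([s.trace for s in sims])
        mm = np.mean(
            [np.mean(est.decode(s.trace) != s.state_at_frames) for s in sims]
        )
        assert mm < 0.05

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            fit_hmm_decode(_trace(np.arange(5.0)))


class TestDwells:
    def test_run_length_arithmetic(self):
        path = [1, 1, 0, 0, 0, 1]
        ds = extract_dwells(path, 15.0)
        assert list(ds.off_durations) == [45.0]
        assert list(ds.off_censored) == [False]
        assert list(ds.on_durations) == [30.0, 15.0]
        assert list(ds.on_censored) == [True, True]

    def test_all_off_path_is_one_censored_video_length_dwell(self):
        ds = extract_dwells(np.zeros(60, dtype=int), 15.0)
        assert len(ds.off_durations) == 1
        assert ds.off_durations[0] == 900.0
        assert ds.off_censored[0]
        assert len(ds.on_durations) == 0

    def test_dwells_concatenate_to_trace_duration(self, rng):
        for _ in range(20):
            path = rng.integers(0, 2, size=rng.integers(2, 120))
            ds = extract_dwells(path, 15.0)
            total = ds.on_durations.sum() + ds.off_durations.sum()
            assert total == pytest.approx(len(path) * 15.0)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            extract_dwells([], 15.0)


class TestExponentialFits:
    def test_mle_is_sample_mean(self):
        ds = DwellSet(
            on_durations=np.array([10.0, 20.0, 30.0, 20.0, 20.0]),
            off_durations=np.array([]),
            on_censored=np.zeros(5, bool),
            off_censored=np.array([], bool),
            experiment_duration=900.0,
        )
        mean, se = fit_dwell_exponential(ds, "on")
        assert mean == pytest.approx(20.0)
        assert se == pytest.approx(20.0 / np.sqrt(5))

    def test_censored_likelihood_exceeds_naive_under_heavy_censoring(self, rng):
        """Brute-force check: when the video is short relative to the dwell,
        survival terms pull the estimate above the naive mean."""
        mu, limit = 50.0, 60.0
        raw = rng.exponential(mu, 400)
        cens = raw > limit
        obs = np.minimum(raw, limit)
        ds = DwellSet(
            on_durations=obs,
            off_durations=np.array([]),
            on_censored=cens,
            off_censored=np.array([], bool),
            experiment_duration=limit,
        )
        naive, _ = fit_dwell_exponential(ds, "on", handle_censoring=False)
        corrected, _ = fit_dwell_exponential(ds, "on", handle_censoring=True)
        assert corrected > naive
        assert corrected == pytest.approx(mu, rel=0.15)

    def test_too_few_dwells_rejected(self):
        ds = DwellSet(
            on_durations=np.array([10.0, 20.0]),
            off_durations=np.array([]),
            on_censored=np.zeros(2, bool),
            off_censored=np.array([], bool),
            experiment_duration=900.0,
        )
        with pytest.raises(ValueError):
            fit_dwell_exponential(ds, "on")


class TestSwitchingRates:
    def test_exact_on_true_sampled_chains(self):
        """The frame-sampled Markov MLE undoes discretization: rates recovered
        from the *true* state-at-frame sequences of simulated traces."""
        params = TelegraphParams(1 / 35, 1 / 36, 2.0, 0.0)
        cfg = TraceSimConfig(15, 900, 5.0, 0.0, "steady")
        sims = simulate_traces(params, cfg, 400, 21)
        r = estimate_switching_rates([s.state_at_frames for s in sims], 15.0)
        assert r.mean_on == pytest.approx(36.0, rel=0.08)
        assert r.mean_off == pytest.approx(35.0, rel=0.08)
        # naive run-length averaging on the same paths is far above truth
        ds = DwellSet.concatenate(
            [extract_dwells(s.state_at_frames, 15.0) for s in sims]
        )
        naive, _ = fit_dwell_exponential(ds, "on")
        assert naive > 45.0

    def test_non_embeddable_chain_rejected(self):
        # perfectly alternating: p01 + p10 = 2
        with pytest.raises(ValueError, match="embeddable"):
            estimate_switching_rates(np.tile([0, 1], 50), 15.0)

    def test_requires_both_states(self):
        with pytest.raises(ValueError):
            estimate_switching_rates(np.zeros(50, int), 15.0)


def test_decoded_active_fraction_matches_stationary_probability():
    """Occupancy of decoded paths ~ a/(a+b) within 0.05 (SNR 5, 15-min frames)."""
    params = TelegraphParams(1 / 35, 1 / 36, 2.0, 0.0)
    cfg = TraceSimConfig(15, 900, 5.0, 2.0, "steady")
    sims = simulate_traces(params, cfg, 150, 13)
    est = TraceHMM(normalize="global", random_state=0).fit([s.trace for s in sims])
    occ = np.mean(np.concatenate([est.decode(s.trace) for s in sims]))
    assert occ == pytest.approx(36.0 / 71.0, abs=0.05)
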