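"""Synthetic-data generators: stationarity, truth records, determinism."""

import numpy as np
import pytest
from scipy import stats

from burstkit import (
    DoseMap,
    NormalizedParams,
    TelegraphParams,
    TraceSimConfig,
    render_image,
    simulate_counts,
    simulate_dose_series,
    simulate_trace,
    simulate_traces,
    telegraph_pmf,
    telegraph_summary,
)
from burstkit.simulate import PAPER_DOSES_UM


class TestCounts:
    def test_no_initiation_means_no_mrna(self):
        counts = simulate_counts(TelegraphParams(1, 1, 0.0, 1.0), 200, "steady", 0)
        assert np.all(counts == 0)

    def test_stationary_mean_matches_closed_form(self):
        p = TelegraphParams(1.5, 1.5, 340.0, 1.0)
        counts = simulate_counts(p, 5000, "steady", 1)
        s = telegraph_summary(p.normalized())
        se = np.sqrt(s.variance / 5000)
        assert abs(counts.mean() - s.mean) < 3 * se  # s.mean = 170

    def test_stationary_distribution_matches_pmf(self):
        """Chi-square goodness of fit of sampled counts vs the analytic PMF."""
        q = NormalizedParams(1.0, 1.5, 20.0)
        counts = simulate_counts(TelegraphParams(1, 1.5, 20, 1.0), 10000, "steady", 7)
        pmf = telegraph_pmf(q, 120)
        edges = np.arange(0, 61, 3)
        obs = np.histogram(counts, bins=list(edges) + [10_000])[0]
        exp = np.array(
            [pmf[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]
            + [1.0 - pmf[:60].sum()]
        )
        keep = exp * len(counts) >= 5
        res = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert res.pvalue > 0.01

    def test_finite_horizon_induction_starts_silent_and_fills_up(self):
        p = TelegraphParams(0.02, 1 / 36, 0.5, 0.005)
        frac = [
            (simulate_counts(p, 300, h, 5) > 0).mean() for h in (30.0, 120.0, 360.0)
        ]
        assert frac[0] < frac[1] < frac[2]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_counts(TelegraphParams(1, 1, 1, 1), 0, "steady", 0)
        with pytest.raises(ValueError):
            simulate_counts(TelegraphParams(1, 1, 1, 0.0), 10, "steady", 0)

    def test_fixed_seed_is_bit_identical(self):
        p = TelegraphParams(1, 1.5, 20, 1.0)
        a = simulate_counts(p, 500, "steady", 9)
        b = simulate_counts(p, 500, "steady", 9)
        assert np.array_equal(a, b)
        c = simulate_counts(p, 50, 30.0, 9)
        d = simulate_counts(p, 50, 30.0, 9)
        assert np.array_equal(c, d)


class TestDoseSeries:
    def test_panel_doses_give_six_groups_with_truth(self):
        series = simulate_dose_series(
            TelegraphParams(0, 1.5, 340.0, 1.0),
            DoseMap(PAPER_DOSES_UM, 1.5 / 9.6),
            50,
            0,
        )
        assert series.table.dose_uM.nunique() == 6
        assert series.truth["beta"] == 1.5
        # alpha = k * dose recorded per dose
        for d in PAPER_DOSES_UM:
            assert series.truth["alpha_per_dose"][d] == pytest.approx(1.5 * d / 9.6)

    def test_means_increase_with_dose(self):
        series = simulate_dose_series(
            TelegraphParams(0, 1.5, 100.0, 1.0), DoseMap([1, 5, 25], 0.2), 3000, 3
        )
        means = series.table.groupby("dose_uM")["mrna_count"].mean()
        assert np.all(np.diff(means.to_numpy()) > 0)

    def test_dosemap_validation(self):
        with pytest.raises(ValueError):
            DoseMap([], 1.0)
        with pytest.raises(ValueError):
            DoseMap([1, 2], 0.0)
        with pytest.raises(ValueError):
            DoseMap([2, 1], 1.0)


class TestTraces:
    def test_always_on_gene_is_always_bright(self):
        cfg = TraceSimConfig(15, 900, 5.0, 0.0, "always_on")
        sim = simulate_trace(TelegraphParams(0.0, 1.0, 5.0, 0.0), cfg, 4)
        # high initiation rate: every trailing window contains initiations
        assert np.all(sim.trace.intensity > 0)
        assert np.all(sim.state_at_frames == 1)

    def test_pulse_mode_has_single_on_interval(self):
        cfg = TraceSimConfig(15, 900, 5.0, 0.0, "pulse")
        for seed in range(10):
            sim = simulate_trace(TelegraphParams(1 / 35, 1 / 36, 2.0, 0.0), cfg, seed)
            s = sim.state_at_frames
            assert np.sum(np.diff(s) == 1) == 0  # never re-activates
            on_states = [st for _, _, st in sim.intervals if st == 1]
            assert len(on_states) <= 1

    def test_steady_hidden_dwells_are_exponential_with_generative_means(self):
        """Interior dwell means match truth up to the fits-inside selection bias.

        Dwells wholly inside a T-min recording under-sample long dwells; for
        exponential dwells of mean mu the depression is O(mu/T), so the check
        allows 2*mu^2/T plus two standard errors.
        """
        params = TelegraphParams(1 / 35, 1 / 36, 2.0, 0.0)
        cfg = TraceSimConfig(15, 900, 5.0, 0.0, "steady")
        sims = simulate_traces(params, cfg, 500, 42)
        on = np.concatenate([s.true_dwells()[0] for s in sims])
        off = np.concatenate([s.true_dwells()[1] for s in sims])
        for dwells, mu in ((on, 36.0), (off, 35.0)):
            slack = 2 * mu**2 / cfg.duration + 2 * dwells.std() / np.sqrt(len(dwells))
            assert abs(dwells.mean() - mu) < slack
            # exponential shape: mean/SD ratio near 1
            assert dwells.mean() / dwells.std() == pytest.approx(1.0, abs=0.05)

    def test_intensity_counts_trailing_window_initiations(self):
        cfg = TraceSimConfig(15, 300, 5.0, 0.0, "always_on")
        sim = simulate_trace(TelegraphParams(0, 1, 2.0, 0.0), cfg, 0)
        t = sim.trace.times[4]
        inits = sim.initiation_times
        expected = np.sum((inits > t - 5.0) & (inits <= t))
        assert sim.trace.intensity[4] == expected

    def test_trace_determinism_and_config_validation(self):
        params = TelegraphParams(1 / 35, 1 / 36, 2.0, 0.0)
        cfg = TraceSimConfig(15, 900, 5.0, 2.0, "steady")
        a = simulate_trace(params, cfg, 3)
        b = simulate_trace(params, cfg, 3)
        assert np.array_equal(a.trace.intensity, b.trace.intensity)
        with pytest.raises(ValueError):
            TraceSimConfig(mode="nonsense")
        with pytest.raises(ValueError):
            TraceSimConfig(frame_interval=0)

    def test_induction_activation_fraction_rises_from_zero(self):
        """After ligand addition the fraction of cells showing a nascent
        signal climbs from zero toward its quasi-steady level with the
        relaxation time 1/(a+b); probe the rising phase."""
        params = TelegraphParams(0.005, 1 / 72, 2.0, 0.0)  # tau ~ 53 min
        cfg = TraceSimConfig(15, 600, 5.0, 0.0, "induction")
        sims = simulate_traces(params, cfg, 300, 8)
        bright = np.array([s.trace.intensity > 0 for s in sims])
        frac = bright.mean(axis=0)  # instantaneous fraction with nascent signal
        assert frac[0] == 0.0
        assert frac[1] > 0
        assert frac[4] > frac[1]
        assert frac[20] > frac[4]


class TestRenderImage:
    def test_blank_noiseless_field_is_constant_background(self):
        f = render_image([], shape=(32, 32), background=7.0)
        assert np.allclose(f.image, 7.0)

    def test_single_spot_integrated_intensity_is_gaussian_integral(self):
        amp, sigma = 40.0, 1.5
        f = render_image([(16.0, 16.0, amp)], shape=(33, 33), psf_sigma=sigma, background=2.0)
        integrated = (f.image - 2.0).sum()
        assert integrated == pytest.approx(amp * 2 * np.pi * sigma**2, rel=1e-3)

    def test_out_of_bounds_spot_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_image([(40.0, 5.0, 10.0)], shape=(32, 32))

    def test_noise_models_are_seeded(self):
        spots = [(10.0, 12.0, 30.0)]
        a = render_image(spots, shape=(32, 32), shot_noise=True, read_noise_sd=1.0, seed=5)
        b = render_image(spots, shape=(32, 32), shot_noise=True, read_noise_sd=1.0, seed=5)
        assert np.array_equal(a.image, b.image)
        c = render_image(spots, shape=(32, 32), shot_noise=True, seed=6)
        assert not np.array_equal(a.image, c.image)
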