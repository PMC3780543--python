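"""Canonical parameter-recovery experiments on synthetic data.

Each function simulates data at published-scale study conditions, runs the
corresponding estimator from this package, and returns the recovered
quantities together with the generative truth and the problem size. They are
the single source used by both the acceptance script and the heavier
integration tests, so the numbers those report are always recomputed from
scratch.

Study conditions (the defaults below): six-dose ligand panel 1.56-50 uM;
shared decay-normalized inactivation beta = 1.5 and initiation gamma = 340
with activation linear in dose (half-max at 9.6 uM); 15-min frames over 15 h
of live imaging with ~36/35-min on/off dwells at 50 uM and 38/35 min at
saturation; 60 cells per dose for dose-response means and 5000 for
distribution fitting.
"""

from __future__ import annotations

import numpy as np

from .hill import HillRegressor
from .hmm import (
    DwellSet,
    TraceHMM,
    calibrate_dwell_means,
    estimate_switching_rates,
    extract_dwells,
    fit_dwell_exponential,
)
from .params import DoseMap, TelegraphParams, TraceSimConfig
from .simulate import PAPER_DOSES_UM, simulate_dose_series, simulate_traces
from .telegraph import TelegraphFitter

__all__ = [
    "dose_series_recovery",
    "trace_dwell_recovery",
    "hill_recovery",
]


def dose_series_recovery(
    seed: int,
    n_cells_per_dose: int = 5000,
    beta: float = 1.5,
    gamma: float = 340.0,
    ec50_uM: float = 9.6,
    doses=PAPER_DOSES_UM,
    bin_width: int = 100,
    n_starts: int = 6,
) -> dict:
    """Joint binned-MLE telegraph fit to a synthetic six-dose series.

    Counts are generated at each dose with alpha = beta * dose / EC50 (pure
    frequency modulation) and shared (beta, gamma); the fit shares (beta,
    gamma) across doses with one free alpha per dose.
    """
    k = beta / ec50_uM  # activation per uM, in decay-normalized units
    series = simulate_dose_series(
        TelegraphParams(0.0, beta, gamma, 1.0),
        DoseMap(doses, k),
        n_cells_per_dose,
        seed,
    )
    est = TelegraphFitter(bin_width=bin_width, n_starts=n_starts, random_state=seed)
    est.fit(series.table.mrna_count.to_numpy(), series.table.dose_uM.to_numpy())
    order = np.argsort(series.table.dose_uM.unique())
    return {
        "beta_hat": est.beta_,
        "gamma_hat": est.gamma_,
        "alpha_hat": est.alpha_[order].tolist(),
        "alpha_true": [series.truth["alpha_per_dose"][d] for d in sorted(doses)],
        "beta_true": beta,
        "gamma_true": gamma,
        "log_likelihood": est.log_likelihood_,
        "n_cells_per_dose": n_cells_per_dose,
        "doses_uM": list(doses),
    }


def trace_dwell_recovery(
    seed: int,
    n_traces: int = 500,
    mean_on_min: float = 36.0,
    mean_off_min: float = 35.0,
    frame_interval: float = 15.0,
    duration: float = 900.0,
    initiation_rate: float = 2.0,
    nascent_dwell: float = 5.0,
    snr: float = 5.0,
    calibrate: bool = True,
) -> dict:
    """HMM decoding + dwell estimation on synthetic transcription-site traces.

    Traces are generated with exponential on/off dwells of the given means;
    the mean on-state intensity is initiation_rate * nascent_dwell nascent
    transcripts, and the noise SD is set from the requested SNR. All traces
    are decoded under one pooled two-state HMM. Dwell means are reported at
    three levels of correction: the naive run-length exponential MLE, the
    frame-sampled Markov-chain rate MLE, and (the headline estimate) the
    simulation-calibrated means that also undo the nascent-window smoothing
    of the decoder.
    """
    params = TelegraphParams(
        a=1.0 / mean_off_min, b=1.0 / mean_on_min, c=initiation_rate, d=0.0
    )
    on_level = initiation_rate * nascent_dwell
    cfg = TraceSimConfig(
        frame_interval=frame_interval,
        duration=duration,
        nascent_dwell=nascent_dwell,
        noise_sd=on_level / snr,
        mode="steady",
    )
    sims = simulate_traces(params, cfg, n_traces, seed)
    est = TraceHMM(normalize="global", random_state=seed).fit([s.trace for s in sims])
    paths = [est.decode(s.trace) for s in sims]

    rates = estimate_switching_rates(paths, frame_interval)
    if calibrate:
        cal = calibrate_dwell_means(
            paths, est, cfg, initiation_rate, seed=seed + 101_323
        )
        mean_on_hat, mean_off_hat = cal["mean_on"], cal["mean_off"]
        se_on, se_off = cal["se_mean_on"], cal["se_mean_off"]
    else:
        mean_on_hat, mean_off_hat = rates.mean_on, rates.mean_off
        se_on, se_off = rates.se_mean_on, rates.se_mean_off
    dwells = DwellSet.concatenate(
        [extract_dwells(p, frame_interval, duration) for p in paths]
    )
    naive_on, _ = fit_dwell_exponential(dwells, "on")
    naive_off, _ = fit_dwell_exponential(dwells, "off")
    total_frames = sum(len(p) for p in paths)
    on_frames = sum(int(p.sum()) for p in paths)
    misclass = float(
        np.mean(
            [np.mean(p != s.state_at_frames) for p, s in zip(paths, sims)]
        )
    )
    return {
        "mean_on_hat": mean_on_hat,
        "mean_off_hat": mean_off_hat,
        "se_mean_on": se_on,
        "se_mean_off": se_off,
        "mean_on_rate_mle": rates.mean_on,
        "mean_off_rate_mle": rates.mean_off,
        "mean_on_naive": naive_on,
        "mean_off_naive": naive_off,
        "active_fraction_pct": 100.0 * on_frames / total_frames,
        "frame_mismatch_vs_truth": misclass,
        "mean_on_true": mean_on_min,
        "mean_off_true": mean_off_min,
        "n_traces": n_traces,
        "n_frames": total_frames,
    }


def hill_recovery(
    seed: int,
    amax: float,
    ec50_uM: float,
    fix_h: float | None = None,
    n_cells_per_dose: int = 60,
    beta: float = 1.5,
    doses=PAPER_DOSES_UM,
) -> dict:
    """Hill fit to telegraph-simulated per-dose mean mRNA values.

    Generative truth: activation linear in dose with half-max at ``ec50_uM``
    and gamma = ``amax``, so the noiseless per-dose means follow exactly
    Hill(amax, ec50, h=1). Per-dose means carry ``n_cells_per_dose``-cell
    sampling noise; the fit is weighted by the per-dose SEM.
    """
    k = beta / ec50_uM
    series = simulate_dose_series(
        TelegraphParams(0.0, beta, amax, 1.0),
        DoseMap(doses, k),
        n_cells_per_dose,
        seed,
    )
    g = series.table.groupby("dose_uM")["mrna_count"]
    means = g.mean()
    sems = g.std(ddof=1) / np.sqrt(g.size())
    est = HillRegressor(fix_h=fix_h).fit(
        means.index.to_numpy(), means.to_numpy(), se=sems.to_numpy()
    )
    return {
        "amax_hat": est.amax_,
        "ec50_hat": est.ec50_,
        "h_hat": est.h_,
        "se": est.se_,
        "amax_true": amax,
        "ec50_true": ec50_uM,
        "mean_response": means.to_dict(),
        "n_cells_per_dose": n_cells_per_dose,
    }
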