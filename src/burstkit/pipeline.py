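"""End-to-end orchestration of the two analysis arcs.

``dose_response``: per-cell mRNA counts per dose (simulated or loaded) ->
joint telegraph fit (shared beta, gamma; per-dose alpha) -> per-dose means ->
Hill fits (free and fixed h) -> a report comparing the two parameterizations
through the frequency-modulation correspondence (A_max ~ gamma, EC50 ~
beta/k, dose ~ alpha).

``trace_kinetics``: transcription-site traces per dose -> pooled two-state
HMM decode -> dwell extraction -> exponential/rate dwell estimates and mean
on-state intensity per dose — the live-cell summary.

Reports are flat JSON plus tidy CSV, written with the seed and a config
hash; re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .hill import HillRegressor
from .hmm import (
    DwellSet,
    TraceHMM,
    estimate_switching_rates,
    extract_dwells,
    fit_dwell_exponential,
)
from .params import DoseMap, TelegraphParams, TraceSimConfig
from .simulate import PAPER_DOSES_UM, simulate_dose_series, simulate_traces
from .telegraph import TelegraphFitter

logger = logging.getLogger("burstkit.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_dose_pipeline", "run_trace_pipeline", "run"]

MODES = ("dose_response", "trace_kinetics", "full_synthetic")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 3):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """Validated run configuration; unknown modes are rejected up front."""

    mode: str = "full_synthetic"
    seed: int = 0
    output_dir: str | None = None
    dose_response: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PipelineError(
                "config", f"mode must be one of {MODES}, got {self.mode!r}", exit_code=2
            )
        self.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: d[k] for k in ("mode", "seed", "output_dir", "dose_response", "traces") if k in d}
        return cls(**known)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "dose_response": self.dose_response,
                "traces": self.traces,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DOSE_DEFAULTS = dict(
    beta=1.5,
    gamma=340.0,
    ec50_uM=9.6,
    doses=list(PAPER_DOSES_UM),
    n_cells_per_dose=60,
    bin_width=100,
    n_starts=6,
    counts_csv=None,
)

TRACE_DEFAULTS = dict(
    doses=[0.0, 3.125, 12.5, 50.0],
    mean_on_min=36.0,
    saturation_mean_off_min=35.0,
    saturation_dose_uM=50.0,
    initiation_rate=2.0,
    nascent_dwell=5.0,
    frame_interval=15.0,
    duration=900.0,
    noise_sd=2.0,
    n_traces_per_dose=40,
    traces_csv=None,
)


def _stage(name: str):
    logger.info("stage %s", name)


def run_dose_pipeline(cfg: RunConfig) -> dict:
    """Fixed-cell arc: counts -> joint telegraph fit -> Hill fits -> report."""
    opt = {**DOSE_DEFAULTS, **cfg.dose_response}

    _stage("counts")
    if opt["counts_csv"]:
        table = bio.read_counts_csv(opt["counts_csv"])
        truth = None
    else:
        k = opt["beta"] / opt["ec50_uM"]
        series = simulate_dose_series(
            TelegraphParams(0.0, opt["beta"], opt["gamma"], 1.0),
            DoseMap(opt["doses"], k),
            int(opt["n_cells_per_dose"]),
            cfg.seed,
        )
        table, truth = series.table, series.truth
    logger.info("counts: %d cells in %d groups", len(table), table.dose_uM.nunique())

    _stage("telegraph_fit")
    try:
        fitter = TelegraphFitter(
            bin_width=int(opt["bin_width"]),
            n_starts=int(opt["n_starts"]),
            random_state=cfg.seed,
        ).fit(table.mrna_count.to_numpy(), table.dose_uM.to_numpy())
    except (RuntimeError, ValueError) as e:
        raise PipelineError("telegraph_fit", str(e)) from e
    doses = np.array(sorted(table.dose_uM.unique()))
    order = [fitter.group_labels_.index(d) for d in doses]
    alpha_by_dose = fitter.alpha_[order]

    _stage("hill_fit")
    g = table[table.dose_uM > 0].groupby("dose_uM")["mrna_count"]
    means, sems = g.mean(), g.std(ddof=1) / np.sqrt(g.size())
    try:
        hill_free = HillRegressor().fit(means.index, means.to_numpy(), se=sems.to_numpy())
        hill_h1 = HillRegressor(fix_h=1.0).fit(
            means.index, means.to_numpy(), se=sems.to_numpy()
        )
    except (RuntimeError, ValueError) as e:
        raise PipelineError("hill_fit", str(e)) from e

    # frequency-modulation correspondence: alpha should be linear in dose,
    # A_max ~ gamma, EC50 ~ beta/k
    pos = doses > 0
    k_hat = float(np.sum(alpha_by_dose[pos] * doses[pos]) / np.sum(doses[pos] ** 2))
    report = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_cells": int(len(table)),
        "doses_uM": doses.tolist(),
        "telegraph": fitter.result_.to_dict(),
        "alpha_by_dose": alpha_by_dose.tolist(),
        "per_dose_mean": means.to_dict(),
        "hill_free": {
            "A_max": hill_free.amax_,
            "EC50": hill_free.ec50_,
            "h": hill_free.h_,
            "se": hill_free.se_,
        },
        "hill_h1": {
            "A_max": hill_h1.amax_,
            "EC50": hill_h1.ec50_,
            "se": hill_h1.se_,
        },
        "correspondence": {
            "A_max_vs_gamma": [hill_free.amax_, fitter.gamma_],
            "EC50_vs_beta_over_k": [hill_free.ec50_, fitter.beta_ / k_hat],
            "activation_scale_hat": k_hat,
        },
    }
    if truth is not None:
        report["truth"] = {k: v for k, v in truth.items() if k != "alpha_per_dose"}

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_counts_csv(table, out / "counts.csv")
        pd.DataFrame(
            {"dose_uM": doses, "alpha_hat": alpha_by_dose}
        ).to_csv(out / "alpha_by_dose.csv", index=False)
        bio.write_json(report, out / "dose_report.json")
    return report


def run_trace_pipeline(cfg: RunConfig) -> dict:
    """Live-cell arc: traces -> HMM decode -> dwell summaries per dose."""
    opt = {**TRACE_DEFAULTS, **cfg.traces}
    frame, duration = float(opt["frame_interval"]), float(opt["duration"])

    # frequency modulation: a = k * dose reaches 1/mean_off at saturation dose
    k = (1.0 / opt["saturation_mean_off_min"]) / opt["saturation_dose_uM"]
    b = 1.0 / opt["mean_on_min"]

    per_dose = []
    ss = np.random.SeedSequence(cfg.seed).spawn(len(opt["doses"]))
    dwell_rows = []
    for sub, dose in zip(ss, opt["doses"]):
        _stage(f"traces dose={dose}")
        a = k * float(dose)
        params = TelegraphParams(a, b, float(opt["initiation_rate"]), 0.0)
        cfg_sim = TraceSimConfig(
            frame_interval=frame,
            duration=duration,
            nascent_dwell=float(opt["nascent_dwell"]),
            noise_sd=float(opt["noise_sd"]),
            mode="steady" if a > 0 else "induction",
        )
        seed = int(sub.generate_state(1)[0] % (2**31 - 1))
        sims = simulate_traces(params, cfg_sim, int(opt["n_traces_per_dose"]), seed)
        traces = [s.trace for s in sims]

        est = TraceHMM(normalize="global", random_state=seed).fit(traces)
        paths = [est.decode(t) for t in traces]
        dwells = DwellSet.concatenate(
            [extract_dwells(p, frame, duration) for p in paths]
        )
        for which in ("on", "off"):
            dur = dwells.durations(which)
            cen = (
                dwells.on_censored if which == "on" else dwells.off_censored
            )
            for d_, c_ in zip(dur, cen):
                dwell_rows.append(
                    {"dose_uM": dose, "state": which, "duration_min": d_, "censored": bool(c_)}
                )

        entry = {"dose_uM": dose, "n_traces": len(traces)}
        on_frames = sum(int(p.sum()) for p in paths)
        total_frames = sum(len(p) for p in paths)
        entry["active_fraction_pct"] = 100.0 * on_frames / total_frames
        entry["mean_ts_intensity"] = float(
            np.mean([t.intensity[p == 1].mean() for t, p in zip(traces, paths) if p.any()])
        ) if on_frames else 0.0
        try:
            rates = estimate_switching_rates(paths, frame)
            entry["mean_on_min"] = rates.mean_on
            entry["mean_off_min"] = rates.mean_off
            entry["se_mean_on"] = rates.se_mean_on
            entry["se_mean_off"] = rates.se_mean_off
        except ValueError:
            entry["mean_on_min"] = None
            entry["mean_off_min"] = None
        try:
            m_on, _ = fit_dwell_exponential(dwells, "on")
            entry["mean_on_naive_min"] = m_on
        except ValueError:
            entry["mean_on_naive_min"] = None
        try:
            m_off, _ = fit_dwell_exponential(dwells, "off")
            entry["mean_off_naive_min"] = m_off
        except ValueError:
            # e.g. vehicle: the single off dwell is censored at video duration
            try:
                m_off, _ = fit_dwell_exponential(dwells, "off", handle_censoring=True)
                entry["mean_off_naive_min"] = m_off
            except ValueError:
                entry["mean_off_naive_min"] = None
        unc_off = dwells.durations("off", censored=False)
        entry["off_censoring_limit_min"] = dwells.experiment_duration
        entry["all_off_censored"] = bool(unc_off.size == 0)
        per_dose.append(entry)

    report = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "per_dose": per_dose,
        "truth": {
            "mean_on_min": opt["mean_on_min"],
            "saturation_mean_off_min": opt["saturation_mean_off_min"],
        },
    }
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(dwell_rows).to_csv(out / "dwells.csv", index=False)
        pd.DataFrame(per_dose).to_csv(out / "trace_summary.csv", index=False)
        bio.write_json(report, out / "trace_report.json")
    return report


def run(cfg: RunConfig) -> dict:
    """Run the arc(s) selected by ``cfg.mode``."""
    if cfg.mode == "dose_response":
        return run_dose_pipeline(cfg)
    if cfg.mode == "trace_kinetics":
        return run_trace_pipeline(cfg)
    return {
        "dose_response": run_dose_pipeline(cfg),
        "trace_kinetics": run_trace_pipeline(cfg),
    }
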