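"""Synthetic data with the statistical structure the analysis assumes.

Three generators mirror the three observables: per-cell mRNA counts from the
telegraph model (the smFISH observable), transcription-site intensity traces
from an exact event-level simulation (the live-cell observable), and
diffraction-limited spot images over painted nuclei/cells (the raw imaging
observable). Every generator records its ground truth for oracle testing.

Steady-state counts are sampled exactly from the stationary law via its
Poisson-beta mixture representation (n ~ Poisson(gamma*p), p ~ Beta(alpha,
beta)) — no burn-in is involved. Finite-horizon (induction) counts and all
traces use the exact stochastic simulation algorithm (Gillespie); frames read
out the state/intensity at frame times, with no tau-leaping anywhere.

A single integer seed is split deterministically per cell/trace/image with
`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import IntensityTrace
from .params import DoseMap, TelegraphParams, TraceSimConfig

__all__ = [
    "simulate_counts",
    "simulate_trace",
    "simulate_dose_series",
    "render_image",
    "TraceSimResult",
    "DoseSeries",
    "SpotField",
    "PAPER_DOSES_UM",
]

# the six-dose ligand panel used throughout the dose-response experiments
PAPER_DOSES_UM = (1.56, 3.125, 6.25, 12.5, 25.0, 50.0)


def _rng_per_item(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# mRNA counts


def _ssa_count(
    rng: np.random.Generator, p: TelegraphParams, horizon: float
) -> int:
    """Exact SSA of (gene state, copy number) from (off, 0) to `horizon` min."""
    t, state, n = 0.0, 0, 0
    while True:
        r_switch = p.a if state == 0 else p.b
        r_init = p.c if state == 1 else 0.0
        r_decay = n * p.d
        total = r_switch + r_init + r_decay
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        u = rng.uniform(0.0, total)
        if u < r_switch:
            state = 1 - state
        elif u < r_switch + r_init:
            n += 1
        else:
            n -= 1
    return n


def simulate_counts(params: TelegraphParams, n_cells: int, horizon, seed: int) -> np.ndarray:
    """Per-cell mRNA counts from the telegraph model.

    ``horizon="steady"`` draws exact stationary samples through the
    Poisson-beta mixture representation of the stationary law (requires
    d > 0). A numeric ``horizon`` (minutes) runs the exact SSA from the
    inactive, zero-mRNA initial condition — the induction scenario.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if horizon == "steady":
        if params.d <= 0:
            raise ValueError("steady-state sampling requires d > 0")
        q = params.normalized()
        rng = np.random.default_rng(seed)
        if q.gamma == 0.0:
            return np.zeros(n_cells, dtype=np.int64)
        if q.beta == 0.0:
            return rng.poisson(q.gamma, size=n_cells).astype(np.int64)
        p_on = rng.beta(q.alpha, q.beta, size=n_cells)
        return rng.poisson(q.gamma * p_on).astype(np.int64)
    horizon = float(horizon)
    if horizon < 0:
        raise ValueError("horizon must be >= 0 minutes or 'steady'")
    rngs = _rng_per_item(seed, n_cells)
    return np.array([_ssa_count(r, params, horizon) for r in rngs], dtype=np.int64)


@dataclass
class DoseSeries:
    """A simulated dose series: tidy counts table plus the generative truth."""

    table: pd.DataFrame
    truth: dict


def simulate_dose_series(
    params_template: TelegraphParams,
    dosemap: DoseMap,
    n_cells_per_dose: int,
    seed: int,
    clone: str = "synthetic",
) -> DoseSeries:
    """Steady-state counts at each dose with a = activation_scale * dose.

    b, c, d are shared across doses (frequency modulation). Returns a tidy
    table (cell_id, dose_uM, clone, mrna_count) and the generative truth.
    """
    frames = []
    truth_alpha = {}
    ss = np.random.SeedSequence(seed).spawn(len(dosemap.doses))
    for sub, dose in zip(ss, dosemap.doses):
        p = TelegraphParams(
            dosemap.activation_rate(dose),
            params_template.b,
            params_template.c,
            params_template.d,
        )
        counts = simulate_counts(
            p, n_cells_per_dose, "steady", int(sub.generate_state(1)[0] % (2**31 - 1))
        )
        truth_alpha[dose] = p.normalized().alpha
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{clone}-{dose:g}-{i}" for i in range(n_cells_per_dose)],
                    "dose_uM": dose,
                    "clone": clone,
                    "mrna_count": counts,
                }
            )
        )
    d = params_template.d
    truth = {
        "alpha_per_dose": truth_alpha,
        "beta": params_template.b / d if d > 0 else None,
        "gamma": params_template.c / d if d > 0 else None,
        "activation_scale": dosemap.activation_scale,
        "doses": list(dosemap.doses),
    }
    return DoseSeries(table=pd.concat(frames, ignore_index=True), truth=truth)


# ---------------------------------------------------------------------------
# transcription-site traces


@dataclass
class TraceSimResult:
    """A simulated trace plus its hidden ground truth."""

    trace: IntensityTrace
    state_at_frames: np.ndarray  # hidden promoter state at each frame
    intervals: list  # (t_start, t_end, state) covering the simulated span
    initiation_times: np.ndarray
    params: TelegraphParams = field(repr=False, default=None)
    config: TraceSimConfig = field(repr=False, default=None)

    def true_dwells(self):
        """Interior (uncensored) on/off dwell durations within the recording."""
        on, off = [], []
        inner = self.intervals[1:-1]
        for t0, t1, s in inner:
            (on if s == 1 else off).append(t1 - t0)
        return np.asarray(on), np.asarray(off)


def _simulate_state_process(
    rng: np.random.Generator, p: TelegraphParams, cfg: TraceSimConfig
) -> tuple[list, np.ndarray]:
    """Exact trajectory of the promoter plus initiation event times.

    Simulation starts at -nascent_dwell so that the intensity window of the
    first frame is properly populated; steady mode draws the initial state
    from the stationary law (the dwell process is then stationary by
    memorylessness).
    """
    a, b, c = p.a, p.b, p.c
    t0 = -cfg.nascent_dwell
    if cfg.mode == "steady":
        if a + b <= 0:
            raise ValueError("steady traces need a + b > 0")
        state = int(rng.random() < a / (a + b))
    elif cfg.mode == "induction":
        state, t0 = 0, 0.0
    elif cfg.mode == "pulse":
        state, a = 1, 0.0  # starts active once; never reactivates
    elif cfg.mode == "always_on":
        state, b = 1, 0.0
    else:  # pragma: no cover - validated by TraceSimConfig
        raise ValueError(cfg.mode)

    t = t0
    intervals = []
    inits = []
    seg_start = t
    while t < cfg.duration:
        r_switch = a if state == 0 else b
        r_init = c if state == 1 else 0.0
        total = r_switch + r_init
        if total <= 0.0:
            t = cfg.duration
            break
        t += rng.exponential(1.0 / total)
        if t >= cfg.duration:
            break
        if rng.uniform(0.0, total) < r_switch:
            intervals.append((seg_start, t, state))
            seg_start = t
            state = 1 - state
        else:
            inits.append(t)
    intervals.append((seg_start, cfg.duration, state))
    return intervals, np.asarray(inits)


def simulate_trace(params: TelegraphParams, cfg: TraceSimConfig, seed: int,
                   trace_id: object = 0) -> TraceSimResult:
    """One transcription-site intensity trace with hidden truth.

    The site intensity at a frame is the number of initiation events inside
    the trailing ``nascent_dwell`` window (each nascent transcript contributes
    one unit while it resides at the site) plus Gaussian noise. Frames sit at
    t = 0, dt, ..., (n-1) dt with n = duration/dt, so each frame stands for
    one frame interval of observation.
    """
    rng = np.random.default_rng(seed)
    intervals, inits = _simulate_state_process(rng, params, cfg)
    n_frames = int(round(cfg.duration / cfg.frame_interval))
    times = np.arange(n_frames) * cfg.frame_interval
    counts = np.searchsorted(inits, times, side="right") - np.searchsorted(
        inits, times - cfg.nascent_dwell, side="right"
    )
    intensity = counts.astype(float)
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=n_frames)

    # hidden state at frame times from the interval cover
    bounds = np.array([iv[0] for iv in intervals] + [intervals[-1][1]])
    idx = np.clip(np.searchsorted(bounds, times, side="right") - 1, 0, len(intervals) - 1)
    states = np.array([intervals[i][2] for i in idx], dtype=int)

    # truth intervals clipped to the recorded span [0, duration]
    clipped = [
        (max(t0, 0.0), t1, s) for (t0, t1, s) in intervals if t1 > 0.0
    ]
    return TraceSimResult(
        trace=IntensityTrace(trace_id=trace_id, times=times, intensity=intensity),
        state_at_frames=states,
        intervals=clipped,
        initiation_times=inits[inits >= 0.0],
        params=params,
        config=cfg,
    )


def simulate_traces(
    params: TelegraphParams, cfg: TraceSimConfig, n_traces: int, seed: int
) -> list[TraceSimResult]:
    """Independent traces with deterministically split seeds."""
    ss = np.random.SeedSequence(seed).spawn(n_traces)
    return [
        simulate_trace(
            params, cfg, int(s.generate_state(1)[0] % (2**31 - 1)), trace_id=i
        )
        for i, s in enumerate(ss)
    ]


# ---------------------------------------------------------------------------
# spot images


@dataclass
class SpotField:
    """A rendered 2-D field plus everything needed to grade analysis on it."""

    image: np.ndarray
    truth_spots: list  # (row, col, amplitude), sub-pixel, pixel-center origin
    psf_sigma: float
    background: float
    nuclei: list = field(default_factory=list)  # (row, col, r_rad, c_rad, level)
    cells: list = field(default_factory=list)

    def truth_sidecar(self) -> dict:
        return {
            "spots": [list(map(float, s)) for s in self.truth_spots],
            "psf_sigma": float(self.psf_sigma),
            "background": float(self.background),
            "nuclei": [list(map(float, e)) for e in self.nuclei],
            "cells": [list(map(float, e)) for e in self.cells],
        }


def _paint_ellipses(canvas: np.ndarray, ellipses) -> None:
    rr, cc = np.mgrid[0 : canvas.shape[0], 0 : canvas.shape[1]]
    for r0, c0, rr_rad, cc_rad, level in ellipses:
        inside = ((rr - r0) / rr_rad) ** 2 + ((cc - c0) / cc_rad) ** 2 <= 1.0
        canvas[inside] += level


def render_image(
    truth_spots,
    shape: tuple[int, int] = (128, 128),
    psf_sigma: float = 1.3,
    background: float = 10.0,
    *,
    shot_noise: bool = False,
    read_noise_sd: float = 0.0,
    seed: int = 0,
    nuclei=None,
    cells=None,
) -> SpotField:
    """Render diffraction-limited spots on a (optionally cell-painted) field.

    Each spot (row, col, amplitude) adds a 2-D Gaussian with peak `amplitude`
    and width `psf_sigma` px, so its integrated signal above background is
    amplitude * 2 pi sigma^2. Coordinates are 0-based (row, col) with spot
    centers measured at pixel centers. Camera model: Poisson shot noise on
    the expected signal plus additive Gaussian read noise.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("image must be at least 16x16 pixels")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    for r0, c0, amp in truth_spots:
        if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
            raise ValueError(f"spot ({r0}, {c0}) outside image bounds")
        if amp <= 0:
            raise ValueError("spot amplitude must be > 0")

    clean = np.full(shape, float(background))
    if cells or nuclei:
        structures = np.zeros(shape)
        if cells:
            _paint_ellipses(structures, cells)
        if nuclei:
            _paint_ellipses(structures, nuclei)
        # the optics blur extended structures too: no step edges on camera
        from scipy.ndimage import gaussian_filter

        clean += gaussian_filter(structures, psf_sigma)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    for r0, c0, amp in truth_spots:
        clean += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * psf_sigma**2))

    rng = np.random.default_rng(seed)
    img = rng.poisson(clean).astype(float) if shot_noise else clean.copy()
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=shape)
    return SpotField(
        image=img,
        truth_spots=[tuple(map(float, s)) for s in truth_spots],
        psf_sigma=float(psf_sigma),
        background=float(background),
        nuclei=list(nuclei or []),
        cells=list(cells or []),
    )
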