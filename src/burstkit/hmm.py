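"""Two-state HMM burst calling on transcription-site intensity traces.

A transcription site toggles between a dark (promoter off, no nascent RNA)
and a bright (actively transcribing) level. Traces are segmented with a
two-state Gaussian-emission hidden Markov model (Baum-Welch + Viterbi, via
hmmlearn, with k-means-based initialization and seeded restarts), decoded
paths are run-length encoded into on/off dwell times with boundary
censoring, and dwell distributions are fit as exponentials.

Frame-sampled dwell estimation
------------------------------
At a 15-min frame interval comparable to the dwell times themselves, naive
run-length dwell means are biased upward: dwells shorter than a frame are
missed, which merges the neighbouring runs of the opposite state. The
decoded frame sequence of a two-state continuous-time Markov process is
itself an exact discrete-time Markov chain, so `estimate_switching_rates`
recovers the continuous-time rates (hence unbiased mean dwell times) from
the decoded chain's transition counts in closed form. The plain
`fit_dwell_exponential` (sample-mean MLE with optional censored likelihood)
is retained for dwell-distribution work at frame intervals much shorter than
the dwells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

# the convergence monitor logs harmless sub-tolerance oscillations
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "IntensityTrace",
    "DwellSet",
    "TraceHMM",
    "SwitchingRates",
    "fit_hmm_decode",
    "extract_dwells",
    "fit_dwell_exponential",
    "estimate_switching_rates",
    "calibrate_dwell_means",
]

OFF, ON = 0, 1


@dataclass(frozen=True)
class IntensityTrace:
    """Time-stamped transcription-site intensity on a uniform frame grid."""

    trace_id: object
    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or x.ndim != 1 or t.size != x.size:
            raise ValueError("times and intensity must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", x)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total observed time; each frame stands for one frame interval."""
        return self.frame_interval * len(self.times)

    def normalized(self, lo_hi: tuple[float, float] | None = None) -> np.ndarray:
        """Unit-interval rescale by the (5th, 95th) percentile window."""
        if lo_hi is None:
            lo, hi = np.percentile(self.intensity, [5.0, 95.0])
        else:
            lo, hi = lo_hi
        span = hi - lo
        if span <= 0:
            return np.zeros_like(self.intensity)
        return (self.intensity - lo) / span


@dataclass
class DwellSet:
    """On/off dwell durations (min) from a decoded path, with censoring."""

    on_durations: np.ndarray
    off_durations: np.ndarray
    on_censored: np.ndarray
    off_censored: np.ndarray
    experiment_duration: float

    def durations(self, which: str, censored: bool | None = None) -> np.ndarray:
        if which not in ("on", "off"):
            raise ValueError("which must be 'on' or 'off'")
        d = self.on_durations if which == "on" else self.off_durations
        c = self.on_censored if which == "on" else self.off_censored
        if censored is None:
            return d
        return d[c == censored]

    @staticmethod
    def concatenate(sets: list["DwellSet"]) -> "DwellSet":
        return DwellSet(
            on_durations=np.concatenate([s.on_durations for s in sets]),
            off_durations=np.concatenate([s.off_durations for s in sets]),
            on_censored=np.concatenate([s.on_censored for s in sets]),
            off_censored=np.concatenate([s.off_censored for s in sets]),
            experiment_duration=max(s.experiment_duration for s in sets),
        )


def _as_array(trace) -> np.ndarray:
    if isinstance(trace, IntensityTrace):
        return trace.intensity
    return np.asarray(trace, dtype=float)


class TraceHMM(BaseEstimator):
    """Two-state Gaussian HMM for transcription-site traces.

    Fit on one trace or pooled over many (shared kinetics and emission
    levels); decode returns Viterbi paths in {0 off, 1 on}, with state 1
    always the higher emission mean.

    Parameters
    ----------
    n_restarts : EM restarts from perturbed k-means initializations.
    normalize : "per-trace" rescales each trace to its own (5,95) percentile
        window (the convention for individually fit traces); "global" uses a
        single window pooled over all fitted traces (appropriate when fitting
        many traces jointly); None fits raw intensities.
    min_separation : if the fitted state means are closer than this many
        pooled emission SDs, the trace set is declared effectively
        single-state (e.g. a vehicle control that never activates) and
        decoding returns all-off.

    Attributes
    ----------
    means_, vars_, transmat_, startprob_ : fitted emission/transition
        parameters, state-ordered (off, on).
    single_state_ : True when the two states are not resolvable.
    """

    def __init__(
        self,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int | None = 0,
        normalize: str | None = "per-trace",
        min_separation: float = 2.0,
    ):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.normalize = normalize
        self.min_separation = min_separation

    # -- helpers -------------------------------------------------------------

    def _norm_values(self, trace) -> np.ndarray:
        x = _as_array(trace)
        if self.normalize == "per-trace":
            lo, hi = np.percentile(x, [5.0, 95.0])
        elif self.normalize == "global":
            lo, hi = self._global_window_
        elif self.normalize is None:
            return x
        else:
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        span = hi - lo
        if span <= 0:
            return np.zeros_like(x)
        return (x - lo) / span

    def _order_states(self, model: GaussianHMM) -> GaussianHMM:
        order = np.argsort(model.means_.ravel())
        model.means_ = model.means_[order]
        model.covars_ = np.maximum(model._covars_[order], 1e-10)
        model.transmat_ = model.transmat_[np.ix_(order, order)]
        model.startprob_ = model.startprob_[order]
        return model

    # -- API -----------------------------------------------------------------

    def fit(self, traces):
        """Fit on a single trace/array or a list of them (pooled EM)."""
        if isinstance(traces, (IntensityTrace, np.ndarray)) or (
            np.ndim(traces) == 1 and not isinstance(traces, (list, tuple))
        ):
            traces = [traces]
        raw = [_as_array(t) for t in traces]
        pooled_raw = np.concatenate(raw)
        self._global_window_ = tuple(np.percentile(pooled_raw, [5.0, 95.0]))
        values = [self._norm_values(t) for t in traces]
        X = np.concatenate(values)[:, None]
        lengths = [len(v) for v in values]

        sd = float(X.std())
        if sd <= 1e-12:
            # genuinely constant data: declared single state
            self.single_state_ = True
            self.means_ = np.array([float(X.mean())] * 2)
            self.vars_ = np.array([1e-10] * 2)
            self.transmat_ = np.eye(2)
            self.startprob_ = np.array([1.0, 0.0])
            self.model_ = None
            return self

        km = KMeans(n_clusters=2, n_init=10, random_state=self.random_state).fit(X)
        centers = np.sort(km.cluster_centers_.ravel())
        spread = max(centers[1] - centers[0], sd)

        rng = np.random.default_rng(self.random_state)
        best, best_ll = None, -np.inf
        for r in range(max(self.n_restarts, 1)):
            model = GaussianHMM(
                n_components=2,
                covariance_type="diag",
                n_iter=self.max_iter,
                tol=self.tol,
                init_params="",
                params="stmc",
                random_state=self.random_state,
                min_covar=1e-6,
            )
            means = centers.copy()
            if r > 0:
                means = means + rng.normal(0.0, 0.25 * spread, size=2)
            model.means_ = means[:, None]
            model.covars_ = np.full((2, 1), (0.5 * spread) ** 2)
            model.startprob_ = np.array([0.5, 0.5])
            model.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model.fit(X, lengths)
                    ll = model.score(X, lengths)
                except (ValueError, np.linalg.LinAlgError):
                    continue
            if ll > best_ll:
                best, best_ll = model, ll
        if best is None:
            raise RuntimeError("HMM fit failed from all restarts")

        best = self._order_states(best)
        self.model_ = best
        self.means_ = best.means_.ravel().copy()
        self.vars_ = best._covars_.ravel().copy()
        self.transmat_ = best.transmat_.copy()
        self.startprob_ = best.startprob_.copy()
        self.log_likelihood_ = float(best_ll)
        pooled_sd = float(np.sqrt(self.vars_.max()))
        self.single_state_ = (
            self.means_[1] - self.means_[0] < self.min_separation * pooled_sd
        )
        return self

    def decode(self, trace) -> np.ndarray:
        """Viterbi path of one trace under the fitted model, in {0, 1}."""
        x = self._norm_values(trace)
        if self.single_state_ or self.model_ is None:
            return np.zeros(len(x), dtype=int)
        _, path = self.model_.decode(x[:, None])
        return path.astype(int)

    def predict_proba(self, trace) -> np.ndarray:
        """Per-frame posterior P(state | trace), columns (off, on)."""
        x = self._norm_values(trace)
        if self.single_state_ or self.model_ is None:
            out = np.zeros((len(x), 2))
            out[:, OFF] = 1.0
            return out
        return self.model_.predict_proba(x[:, None])

    def score(self, traces) -> float:
        if isinstance(traces, (IntensityTrace, np.ndarray)):
            traces = [traces]
        values = [self._norm_values(t) for t in traces]
        X = np.concatenate(values)[:, None]
        if self.model_ is None:
            return float("nan")
        return float(self.model_.score(X, [len(v) for v in values]))


def fit_hmm_decode(trace, *, seed: int | None = 0, n_restarts: int = 5,
                   normalize: str | None = "per-trace"):
    """Fit a two-state HMM to a single trace and decode it.

    Returns ``(estimator, viterbi_path, posteriors)``. The estimator is a
    fitted `TraceHMM`; paths are in {0 off, 1 on}.
    """
    x = _as_array(trace)
    if len(x) < 10:
        raise ValueError("need at least 10 frames to fit an HMM")
    est = TraceHMM(n_restarts=n_restarts, random_state=seed, normalize=normalize)
    est.fit(trace)
    return est, est.decode(trace), est.predict_proba(trace)


def extract_dwells(path, frame_interval: float, duration: float | None = None) -> DwellSet:
    """Run-length encode a decoded {0,1} path into dwell times.

    Each frame stands for one frame interval, so a run of k frames is a
    dwell of k * frame_interval minutes and dwell times sum to the trace
    duration. The first and last runs touch the recording boundary and are
    flagged censored (their true durations are only bounded below).
    """
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("empty state path")
    if duration is None:
        duration = float(len(path) * frame_interval)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    states = path[starts]
    lengths = (ends - starts) * frame_interval
    censored = np.zeros(len(starts), dtype=bool)
    censored[0] = True
    censored[-1] = True
    on = states == ON
    return DwellSet(
        on_durations=lengths[on],
        off_durations=lengths[~on],
        on_censored=censored[on],
        off_censored=censored[~on],
        experiment_duration=float(duration),
    )


def fit_dwell_exponential(
    dwells: DwellSet, which: str, handle_censoring: bool = False
) -> tuple[float, float]:
    """Exponential MLE of the mean dwell time; returns ``(mean, se)``.

    Without censoring handling the estimate is the sample mean of the
    uncensored dwells. With ``handle_censoring`` the boundary-censored dwells
    contribute survival terms, giving mean = (total observed time)/(number of
    uncensored dwells). SE from the observed Fisher information.
    """
    unc = dwells.durations(which, censored=False)
    cen = dwells.durations(which, censored=True)
    if handle_censoring:
        if len(unc) < 1 or len(unc) + len(cen) < 5:
            raise ValueError("too few dwells for a censored-likelihood fit")
        mean = float((unc.sum() + cen.sum()) / len(unc))
    else:
        if len(unc) < 5:
            raise ValueError(
                "need >= 5 uncensored dwells (or use handle_censoring=True)"
            )
        mean = float(unc.mean())
    se = mean / np.sqrt(len(unc))
    return mean, se


@dataclass(frozen=True)
class SwitchingRates:
    """Continuous-time two-state switching rates from a frame-sampled path."""

    k_on: float  # off -> on, 1/min (burst frequency)
    k_off: float  # on -> off, 1/min
    mean_on: float  # 1/k_off, min
    mean_off: float  # 1/k_on, min
    se_mean_on: float
    se_mean_off: float
    n_frames: int


def estimate_switching_rates(paths, frame_interval: float) -> SwitchingRates:
    """MLE of the underlying switching rates from decoded frame sequences.

    The frame-sampled state of a two-state continuous-time Markov process is
    an exact discrete-time Markov chain with transition probabilities
    p01 = pi_on (1 - e^(-r dt)), p10 = pi_off (1 - e^(-r dt)), r = k_on+k_off.
    Estimating (p01, p10) by transition counting and inverting gives unbiased
    dwell means even when dwells are comparable to the frame interval —
    unlike run-length averaging, which misses sub-frame dwells and merges
    the neighbouring runs.
    """
    if isinstance(paths, np.ndarray) and paths.ndim == 1:
        paths = [paths]
    n = np.zeros((2, 2))
    total = 0
    for p in paths:
        p = np.asarray(p, dtype=int)
        total += len(p)
        for i in (0, 1):
            for j in (0, 1):
                n[i, j] += int(np.sum((p[:-1] == i) & (p[1:] == j)))
    n0, n1 = n[0].sum(), n[1].sum()
    if n0 == 0 or n1 == 0:
        raise ValueError("need transitions observed out of both states")
    p01 = n[0, 1] / n0
    p10 = n[1, 0] / n1
    s = p01 + p10
    if s <= 0 or s >= 1:
        raise ValueError(
            "sampled chain is not embeddable in a two-state CT process "
            f"(p01 + p10 = {s:.3f} not in (0, 1)); frames may be too sparse"
        )

    def rates(p01_, p10_):
        s_ = p01_ + p10_
        r = -np.log(1.0 - s_) / frame_interval
        return (p01_ / s_) * r, (p10_ / s_) * r  # k_on, k_off

    k_on, k_off = rates(p01, p10)
    # delta-method SEs via numerical sensitivities to (p01, p10)
    var01 = p01 * (1 - p01) / n0
    var10 = p10 * (1 - p10) / n1
    eps = 1e-6
    d_on = np.array(
        [
            (rates(p01 + eps, p10)[0] - k_on) / eps,
            (rates(p01, p10 + eps)[0] - k_on) / eps,
        ]
    )
    d_off = np.array(
        [
            (rates(p01 + eps, p10)[1] - k_off) / eps,
            (rates(p01, p10 + eps)[1] - k_off) / eps,
        ]
    )
    var_kon = d_on[0] ** 2 * var01 + d_on[1] ** 2 * var10
    var_koff = d_off[0] ** 2 * var01 + d_off[1] ** 2 * var10
    return SwitchingRates(
        k_on=float(k_on),
        k_off=float(k_off),
        mean_on=float(1.0 / k_off),
        mean_off=float(1.0 / k_on),
        se_mean_on=float(np.sqrt(var_koff) / k_off**2),
        se_mean_off=float(np.sqrt(var_kon) / k_on**2),
        n_frames=int(total),
    )


def calibrate_dwell_means(
    paths,
    decoder: TraceHMM,
    config,
    initiation_rate: float,
    seed: int = 0,
    n_sim_traces: int | None = None,
    max_iter: int = 12,
    rtol: float = 0.02,
) -> dict:
    """Simulation-calibrated dwell means (indirect inference).

    Even the frame-sampled rate MLE retains a residual upward bias when the
    nascent-signal residence window hides sub-window dwells from the decoder.
    This estimator removes it by self-consistency: candidate dwell means are
    iterated until traces simulated at the candidate kinetics — pushed
    through the *same* fitted decoder and the same rate statistic — reproduce
    the statistic observed on the data. Common random numbers (a fixed seed)
    keep the matching deterministic.

    Parameters
    ----------
    paths : decoded {0,1} frame sequences of the observed traces.
    decoder : the `TraceHMM` fitted on the observed traces.
    config : the acquisition/emission settings (`TraceSimConfig`) assumed for
        the observation process — frame interval, duration, nascent residence
        time and noise level.
    initiation_rate : assumed initiation rate while active (1/min); with
        ``config.nascent_dwell`` it sets the simulated on-state brightness.

    Returns a dict with the calibrated ``mean_on``/``mean_off`` (min), the
    uncalibrated rate-MLE values, and convergence diagnostics.
    """
    from .params import TelegraphParams
    from .simulate import simulate_traces  # local import: avoid module cycle

    if n_sim_traces is None:
        n_sim_traces = len(paths)
    obs = estimate_switching_rates(paths, config.frame_interval)
    target = np.array([obs.mean_on, obs.mean_off])
    theta = target.copy()
    history = []
    converged = False
    for it in range(max_iter):
        params = TelegraphParams(
            a=1.0 / theta[1], b=1.0 / theta[0], c=initiation_rate, d=0.0
        )
        sims = simulate_traces(params, config, n_sim_traces, seed)
        sim_paths = [decoder.decode(s.trace) for s in sims]
        m = estimate_switching_rates(sim_paths, config.frame_interval)
        model = np.array([m.mean_on, m.mean_off])
        ratio = target / model
        history.append({"theta": theta.tolist(), "model": model.tolist()})
        if np.all(np.abs(ratio - 1.0) < rtol):
            converged = True
            break
        theta = np.clip(theta * ratio, 1e-3, None)
    return {
        "mean_on": float(theta[0]),
        "mean_off": float(theta[1]),
        "mean_on_uncalibrated": float(obs.mean_on),
        "mean_off_uncalibrated": float(obs.mean_off),
        "se_mean_on": float(obs.se_mean_on * np.sqrt(2.0)),  # sim noise adds ~equally
        "se_mean_off": float(obs.se_mean_off * np.sqrt(2.0)),
        "converged": converged,
        "n_iterations": len(history),
        "history": history,
    }
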