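"""Steady-state mRNA distribution of the random telegraph model and its MLE.

The two-state gene (activation rate ``a``, inactivation ``b``, initiation
``c``, decay ``d``; snapshots identify only alpha=a/d, beta=b/d, gamma=c/d)
has the stationary copy-number law

    P(n) = [G(alpha+n) G(alpha+beta)] / [G(n+1) G(alpha+beta+n) G(alpha)]
           * gamma**n * 1F1(alpha+n; alpha+beta+n; -gamma)

(G the gamma function, 1F1 Kummer's confluent hypergeometric function), the
Poisson-beta mixture n ~ Poisson(gamma*p), p ~ Beta(alpha, beta).

Naive evaluation of 1F1 overflows already around gamma ~ 100, so the PMF is
computed in log space after the Kummer transformation
1F1(alpha+n; alpha+beta+n; -gamma) = exp(-gamma) * 1F1(beta; alpha+beta+n; gamma),
whose series has all-positive terms and is summed with log-sum-exp. An
independent brute-force oracle (`cme_oracle`) solves the truncated chemical
master equation directly and shares no code with `telegraph_pmf`.

Fitting maximizes the multinomial likelihood of *binned* copy-number
histograms (the bin probability is the PMF summed over the bin, the last bin
open-ended), either per group with all three parameters free or jointly
across a dose series with shared (beta, gamma) and one alpha per dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import spsolve
from scipy.special import gammaln
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .params import NormalizedParams

__all__ = [
    "telegraph_pmf",
    "telegraph_summary",
    "TelegraphSummary",
    "cme_oracle",
    "default_n_max",
    "TelegraphFitter",
    "TelegraphFitResult",
    "fit_counts",
]


def _as_params(p) -> NormalizedParams:
    if isinstance(p, NormalizedParams):
        return p
    alpha, beta, gamma = p
    return NormalizedParams(float(alpha), float(beta), float(gamma))


@dataclass(frozen=True)
class TelegraphSummary:
    mean: float
    active_fraction: float
    fano: float

    @property
    def variance(self) -> float:
        return self.fano * self.mean


def telegraph_summary(p) -> TelegraphSummary:
    """Closed-form stationary moments.

    mean = gamma * alpha/(alpha+beta); active_fraction = alpha/(alpha+beta);
    Fano = 1 + gamma*beta / [(alpha+beta)(1+alpha+beta)].
    """
    p = _as_params(p)
    ab = p.alpha + p.beta
    if ab <= 0:
        raise ValueError("alpha + beta must be > 0")
    f = p.alpha / ab
    mean = p.gamma * f
    fano = 1.0 + p.gamma * p.beta / (ab * (1.0 + ab))
    return TelegraphSummary(mean=mean, active_fraction=f, fano=fano)


def default_n_max(p, sd_mult: float = 12.0) -> int:
    """Truncation point capturing essentially all stationary mass."""
    s = telegraph_summary(p)
    return int(np.ceil(s.mean + sd_mult * np.sqrt(s.variance) + 60))


def _log_kummer_series(beta: float, ab: float, gamma: float, n_max: int) -> np.ndarray:
    """log 1F1(beta; ab + n; gamma) for n = 0..n_max, all-positive-term series."""
    # series terms t_k = (beta)_k / (ab+n)_k * gamma^k / k!; tail decays like
    # Poisson(gamma), so k up to gamma + 12*sqrt(gamma) covers it to ~1e-12
    n_terms = int(np.ceil(gamma + 12.0 * np.sqrt(gamma + 25.0) + 40.0))
    k = np.arange(n_terms + 1)
    log_ck = gammaln(beta + k) - gammaln(beta) + k * np.log(gamma) - gammaln(k + 1)
    m = np.arange(n_max + n_terms + 1)
    g = gammaln(ab + m)  # g[m] = log G(ab + m): the lattice trick — (ab+n)_k = G(ab+n+k)/G(ab+n)
    n = np.arange(n_max + 1)
    out = np.empty(n_max + 1)
    block = max(1, int(4e6 // (n_terms + 1)))  # bound the working set
    for lo in range(0, n_max + 1, block):
        nb = n[lo : lo + block]
        terms = log_ck[None, :] + g[nb, None] - g[nb[:, None] + k[None, :]]
        peak = terms.max(axis=1, keepdims=True)
        out[lo : lo + block] = peak[:, 0] + np.log(np.exp(terms - peak).sum(axis=1))
    return out


def telegraph_pmf(p, n_max: int, *, tail_warn: float = 1e-6) -> np.ndarray:
    """Stationary telegraph PMF on counts 0..n_max.

    Entries are non-negative and sum to 1 minus the truncated tail mass; a
    warning is raised when that tail exceeds ``tail_warn``.
    """
    p = _as_params(p)
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    n = np.arange(n_max + 1)
    if p.gamma == 0.0:
        pmf = np.zeros(n_max + 1)
        pmf[0] = 1.0
        return pmf
    if p.beta == 0.0:
        # gene always on: Poisson(gamma)
        logpmf = n * np.log(p.gamma) - p.gamma - gammaln(n + 1)
    else:
        ab = p.alpha + p.beta
        log1f1 = _log_kummer_series(p.beta, ab, p.gamma, n_max)
        logpmf = (
            gammaln(p.alpha + n)
            + gammaln(ab)
            - gammaln(n + 1)
            - gammaln(ab + n)
            - gammaln(p.alpha)
            + n * np.log(p.gamma)
            - p.gamma
            + log1f1
        )
    pmf = np.exp(logpmf)
    tail = 1.0 - pmf.sum()
    if tail > tail_warn:
        warnings.warn(
            f"truncation at n_max={n_max} leaves {tail:.3g} probability mass "
            f"beyond the grid (> {tail_warn:g}); increase n_max",
            RuntimeWarning,
            stacklevel=2,
        )
    return pmf


def cme_oracle(p, n_max: int) -> np.ndarray:
    """Brute-force stationary law from the truncated master equation.

    Builds the generator over (gene state, copy number) with time in units of
    1/d, solves its null vector by sparse LU, and marginalizes over the gene
    state. Independent of `telegraph_pmf` — used as its oracle.
    """
    p = _as_params(p)
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    n_states = 2 * (n_max + 1)  # state index 2*n + g, g=1 active

    rows, cols, vals = [], [], []

    def add(i: int, j: int, rate: float) -> None:
        if rate == 0.0:
            return
        rows.append(j)  # build Q^T directly: flow into j' from i
        cols.append(i)
        vals.append(rate)
        rows.append(i)
        cols.append(i)
        vals.append(-rate)

    for n in range(n_max + 1):
        off, on = 2 * n, 2 * n + 1
        add(off, on, p.alpha)
        add(on, off, p.beta)
        if n < n_max:
            add(on, on + 2, p.gamma)
        for g in (off, on):
            if n > 0:
                add(g, g - 2, float(n))

    qt = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    ).tolil()
    # replace last balance equation with the normalization constraint
    qt[n_states - 1, :] = 1.0
    rhs = np.zeros(n_states)
    rhs[-1] = 1.0
    pi = spsolve(sparse.csc_matrix(qt), rhs)
    if not np.all(np.isfinite(pi)):
        raise np.linalg.LinAlgError("singular or ill-conditioned CME truncation")
    pi = np.clip(pi, 0.0, None)
    marginal = pi[0::2] + pi[1::2]
    boundary = marginal[-1]
    if boundary > 1e-8:
        warnings.warn(
            f"CME truncation boundary holds {boundary:.3g} mass; increase n_max",
            RuntimeWarning,
            stacklevel=2,
        )
    return marginal / pi.sum()


# ---------------------------------------------------------------------------
# Binned maximum-likelihood fitting


def _bin_histogram(counts: np.ndarray, bin_width: int) -> np.ndarray:
    """Observed frequencies per bin; the final bin is open-ended."""
    idx = counts // bin_width
    n_bins = int(idx.max()) + 1
    return np.bincount(idx, minlength=n_bins).astype(float)


def _bin_probs(p: NormalizedParams, n_bins: int, bin_width: int) -> np.ndarray:
    """Multinomial cell probabilities: PMF summed over each bin, last open."""
    if n_bins == 1:
        return np.array([1.0])
    edge = (n_bins - 1) * bin_width  # pmf needed on 0..edge-1
    pmf = telegraph_pmf(p, edge - 1, tail_warn=np.inf)
    closed = pmf.reshape(n_bins - 1, bin_width).sum(axis=1)
    probs = np.empty(n_bins)
    probs[:-1] = closed
    probs[-1] = max(1.0 - closed.sum(), 0.0)
    return probs


@dataclass
class TelegraphFitResult:
    """Point estimates and diagnostics of a (joint) telegraph fit."""

    alpha: np.ndarray
    beta: float
    gamma: float
    group_labels: list
    log_likelihood: float
    converged: bool
    n_starts: int
    boundary_flags: dict = field(default_factory=dict)
    ci: dict | None = None

    def params_for(self, label) -> NormalizedParams:
        i = self.group_labels.index(label)
        return NormalizedParams(float(self.alpha[i]), self.beta, self.gamma)

    def to_dict(self) -> dict:
        out = {
            "alpha": {str(l): float(a) for l, a in zip(self.group_labels, self.alpha)},
            "beta": float(self.beta),
            "gamma": float(self.gamma),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_starts": int(self.n_starts),
            "boundary_flags": self.boundary_flags,
        }
        if self.ci is not None:
            out["ci"] = self.ci
        return out


_LOG_BOUNDS_ALPHA = (np.log(1e-4), np.log(1e4))
_LOG_BOUNDS_BETA = (np.log(1e-4), np.log(1e4))
_LOG_BOUNDS_GAMMA = (np.log(1e-2), np.log(1e6))


class TelegraphFitter(BaseEstimator):
    """Maximum-likelihood telegraph fit to binned mRNA copy-number histograms.

    With one group all three normalized parameters (alpha, beta, gamma) are
    free; with several groups (a dose series) beta and gamma are shared and
    each group gets its own activation parameter alpha — the
    frequency-modulation parameterization. Optimization is bounded
    quasi-Newton on log-parameters with seeded Latin-hypercube multi-starts
    around a method-of-moments guess.

    Parameters
    ----------
    bin_width : histogram bin size in mRNA counts (the field convention for
        this reporter is 100).
    n_starts : number of multi-start optimizations.
    random_state : seed for the multi-start design and the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    alpha_ : per-group activation estimates, ordered as ``group_labels_``.
    beta_, gamma_ : shared inactivation / initiation estimates.
    log_likelihood_ : multinomial log-likelihood at the optimum.
    result_ : full `TelegraphFitResult`.
    """

    def __init__(
        self,
        bin_width: int = 100,
        n_starts: int = 8,
        random_state: int | None = 0,
        max_iter: int = 400,
        boundary_tol: float = 1e-3,
    ):
        self.bin_width = bin_width
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_iter = max_iter
        self.boundary_tol = boundary_tol

    # -- internals ----------------------------------------------------------

    def _prepare(self, counts, groups):
        counts = np.asarray(counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D array of per-cell totals")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        if groups is None:
            groups = np.zeros(len(counts), dtype=int)
        groups = np.asarray(groups)
        labels = list(pd.unique(groups))
        hists = []
        for lab in labels:
            sub = counts[groups == lab]
            if sub.size < 10:
                raise ValueError(f"group {lab!r} has < 10 cells")
            hists.append(_bin_histogram(sub, self.bin_width))
        return labels, hists

    def _nll(self, theta: np.ndarray, hists) -> float:
        g = len(hists)
        log_beta, log_gamma = theta[0], theta[1]
        beta, gamma = np.exp(log_beta), np.exp(log_gamma)
        total = 0.0
        for i in range(g):
            alpha = np.exp(theta[2 + i])
            try:
                p = NormalizedParams(alpha, beta, gamma)
                probs = _bin_probs(p, len(hists[i]), self.bin_width)
            except (ValueError, FloatingPointError):
                return 1e12
            obs = hists[i]
            if np.any((probs <= 0) & (obs > 0)):
                return 1e12
            keep = obs > 0
            total -= float(np.sum(obs[keep] * np.log(probs[keep])))
        if not np.isfinite(total):
            return 1e12
        return total

    def _moment_init(self, hists) -> np.ndarray:
        bw = self.bin_width
        means, maxima = [], []
        for h in hists:
            centers = (np.arange(len(h)) + 0.5) * bw
            m = float(np.sum(h * centers) / h.sum())
            means.append(m)
            maxima.append(len(h) * bw)
        gamma0 = max(max(maxima), 1.5 * max(means), 1.0)
        beta0 = 1.0
        alpha0 = [beta0 * m / max(gamma0 - m, 0.05 * gamma0) for m in means]
        alpha0 = [max(a, 1e-3) for a in alpha0]
        return np.log(np.array([beta0, gamma0, *alpha0]))

    def _starts(self, theta0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.n_starts <= 1:
            return theta0[None, :]
        sampler = qmc.LatinHypercube(d=theta0.size, seed=rng)
        # multiplicative perturbations in [1/6, 6] around the moment guess
        jitter = (sampler.random(self.n_starts - 1) * 2.0 - 1.0) * np.log(6.0)
        return np.vstack([theta0, theta0[None, :] + jitter])

    # -- API ----------------------------------------------------------------

    def fit(self, counts, groups=None):
        """Fit to per-cell counts; ``groups`` labels the dose series groups."""
        labels, hists = self._prepare(counts, groups)
        g = len(hists)
        rng = np.random.default_rng(self.random_state)
        theta0 = self._moment_init(hists)
        # gamma cannot exceed the data range by much: the conditional law given
        # a long active period is Poisson(gamma), so cap it at 30x the top bin
        max_edge = max(len(h) for h in hists) * self.bin_width
        gamma_hi = min(np.log(30.0 * max_edge), _LOG_BOUNDS_GAMMA[1])
        bounds = [_LOG_BOUNDS_BETA, (_LOG_BOUNDS_GAMMA[0], gamma_hi)] + [
            _LOG_BOUNDS_ALPHA
        ] * g

        best = None
        for start in self._starts(theta0, rng):
            res = optimize.minimize(
                self._nll,
                np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds]),
                args=(hists,),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-9 or (
                abs(res.fun - best.fun) <= 1e-9 and res.x[1] < best.x[1]
            ):
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError("telegraph fit failed to converge from any start")

        theta = best.x
        self.beta_ = float(np.exp(theta[0]))
        self.gamma_ = float(np.exp(theta[1]))
        self.alpha_ = np.exp(theta[2:])
        self.group_labels_ = labels
        self.log_likelihood_ = -float(best.fun)
        self.n_iter_ = int(best.nit)

        flags = {}
        for name, val, (lo, hi) in zip(
            ["beta", "gamma"], theta[:2], [_LOG_BOUNDS_BETA, _LOG_BOUNDS_GAMMA]
        ):
            if val - lo < self.boundary_tol or hi - val < self.boundary_tol:
                flags[name] = "at_bound"
        for lab, val in zip(labels, theta[2:]):
            lo, hi = _LOG_BOUNDS_ALPHA
            if val - lo < self.boundary_tol or hi - val < self.boundary_tol:
                flags[f"alpha[{lab}]"] = "at_bound"

        self.result_ = TelegraphFitResult(
            alpha=self.alpha_.copy(),
            beta=self.beta_,
            gamma=self.gamma_,
            group_labels=labels,
            log_likelihood=self.log_likelihood_,
            converged=bool(best.success),
            n_starts=self.n_starts,
            boundary_flags=flags,
        )
        self._hists = hists
        return self

    def log_likelihood(self, counts, groups=None) -> float:
        """Multinomial log-likelihood of new data under the fitted parameters."""
        labels, hists = self._prepare(counts, groups)
        theta = np.log(np.array([self.beta_, self.gamma_, *[
            self.alpha_[self.group_labels_.index(l)] for l in labels
        ]]))
        return -self._nll(theta, hists)

    def bootstrap(self, n_boot: int = 200, seed: int | None = None) -> dict:
        """Parametric-bootstrap 95% CIs; resamples from the fitted law."""
        from .simulate import simulate_counts  # local import: avoid cycle
        from .params import TelegraphParams

        if not hasattr(self, "result_"):
            raise RuntimeError("fit before bootstrap")
        rng = np.random.default_rng(self.random_state if seed is None else seed)
        sizes = [int(h.sum()) for h in self._hists]
        reps = {"beta": [], "gamma": [], "alpha": []}
        for _ in range(n_boot):
            counts, groups = [], []
            for lab, a, n in zip(self.group_labels_, self.alpha_, sizes):
                tp = TelegraphParams(a, self.beta_, self.gamma_, 1.0)
                counts.append(
                    simulate_counts(tp, n, "steady", int(rng.integers(2**31 - 1)))
                )
                groups.append(np.repeat(lab, n))
            refit = TelegraphFitter(
                bin_width=self.bin_width,
                n_starts=1,
                random_state=int(rng.integers(2**31 - 1)),
                max_iter=self.max_iter,
            ).fit(np.concatenate(counts), np.concatenate(groups))
            reps["beta"].append(refit.beta_)
            reps["gamma"].append(refit.gamma_)
            reps["alpha"].append(refit.alpha_)
        ci = {
            k: np.percentile(np.asarray(v), [2.5, 97.5], axis=0).tolist()
            for k, v in reps.items()
        }
        self.result_.ci = ci
        return ci


def fit_counts(
    table: pd.DataFrame,
    *,
    bin_width: int = 100,
    n_starts: int = 8,
    seed: int | None = 0,
    group_col: str = "dose_uM",
    count_col: str = "mrna_count",
    n_boot: int = 0,
) -> TelegraphFitResult:
    """Fit a copy-number table (columns ``dose_uM``, ``mrna_count``) jointly.

    Thin wrapper over `TelegraphFitter`; groups are the unique values of
    ``group_col`` in order of appearance.
    """
    est = TelegraphFitter(bin_width=bin_width, n_starts=n_starts, random_state=seed)
    est.fit(table[count_col].to_numpy(), table[group_col].to_numpy())
    if n_boot:
        est.bootstrap(n_boot=n_boot)
    return est.result_
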