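"""Hill dose-response fitting and the Hill-telegraph correspondence.

The population dose response is modeled as

    activity(x) = A_max * x**h / (EC50**h + x**h)

with saturation level A_max, half-maximal dose EC50 and Hill coefficient h.
Under frequency modulation of the telegraph model — activation rate a = k*x,
b, c, d fixed — the stationary mean <N>(x) = (c/d) * a/(a+b) is *exactly*
this curve with h = 1, A_max = c/d and EC50 = b/k: a first-order Hill
response is mathematically equivalent to pure burst-frequency modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["HillParams", "hill_curve", "HillRegressor", "fit_hill"]


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: saturation, half-max dose (uM), coefficient."""

    A_max: float
    EC50: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.A_max >= 0):
            raise ValueError("A_max must be >= 0")
        if not (self.EC50 > 0):
            raise ValueError("EC50 must be > 0")
        if not (self.h > 0):
            raise ValueError("h must be > 0")


def hill_curve(p: HillParams, doses) -> np.ndarray:
    """Hill activity at the given doses (0 at dose 0, A_max at saturation)."""
    x = np.asarray(doses, dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")
    xh = np.where(x > 0, x, np.nan) ** p.h
    out = p.A_max * xh / (p.EC50**p.h + xh)
    return np.where(x > 0, out, 0.0)


class HillRegressor(BaseEstimator, RegressorMixin):
    """Weighted nonlinear least-squares Hill fit.

    Parameters
    ----------
    fix_h : freeze the Hill coefficient at this value (the two-parameter
        fit); None fits all three parameters.

    Attributes
    ----------
    amax_, ec50_, h_ : point estimates.
    se_ : dict of standard errors from the parameter covariance.
    params_ : the fitted `HillParams`.
    residuals_ : response minus fit at the training doses.
    """

    def __init__(self, fix_h: float | None = None, max_nfev: int = 10000):
        self.fix_h = fix_h
        self.max_nfev = max_nfev

    def fit(self, doses, responses, se=None):
        x = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(responses, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("doses and responses must have equal length")
        if np.any(x < 0):
            raise ValueError("doses must be >= 0")
        n_free = 2 if self.fix_h is not None else 3
        n_distinct = len(np.unique(x[x > 0]))
        if n_distinct < n_free:
            raise ValueError(
                f"need >= {n_free} distinct positive doses, got {n_distinct}"
            )
        sigma = None
        if se is not None:
            sigma = np.asarray(se, dtype=float).ravel()
            if np.any(sigma <= 0):
                raise ValueError("standard errors must be > 0")

        # initialization: A_max <- max response, EC50 <- dose nearest half-max
        a0 = float(y.max()) if y.max() > 0 else 1.0
        pos = x > 0
        e0 = float(x[pos][np.argmin(np.abs(y[pos] - a0 / 2.0))])
        e0 = max(e0, np.min(x[pos]) * 0.1)

        if self.fix_h is not None:
            h = float(self.fix_h)

            def f(x_, amax, ec50):
                return hill_curve(HillParams(max(amax, 0.0), max(ec50, 1e-12), h), x_)

            p0, lo, hi = [a0, e0], [0.0, 1e-9], [np.inf, np.inf]
        else:

            def f(x_, amax, ec50, h_):
                return hill_curve(
                    HillParams(max(amax, 0.0), max(ec50, 1e-12), max(h_, 1e-6)), x_
                )

            p0, lo, hi = [a0, e0, 1.0], [0.0, 1e-9, 1e-3], [np.inf, np.inf, 20.0]

        popt, pcov = curve_fit(
            f,
            x,
            y,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=(lo, hi),
            max_nfev=self.max_nfev,
        )
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        self.amax_ = float(popt[0])
        self.ec50_ = float(popt[1])
        self.h_ = float(self.fix_h) if self.fix_h is not None else float(popt[2])
        self.se_ = {"A_max": float(perr[0]), "EC50": float(perr[1])}
        if self.fix_h is None:
            self.se_["h"] = float(perr[2])
        self.params_ = HillParams(self.amax_, self.ec50_, self.h_)
        self.residuals_ = y - hill_curve(self.params_, x)
        if sigma is not None:
            self.weighted_rss_ = float(np.sum((self.residuals_ / sigma) ** 2))
        else:
            self.weighted_rss_ = float(np.sum(self.residuals_**2))
        return self

    def predict(self, doses) -> np.ndarray:
        return hill_curve(self.params_, doses)


def fit_hill(doses, responses, errors=None, fix_h: float | None = None):
    """Weighted Hill fit; returns ``(HillParams, se_dict)``.

    Weights are 1/SE^2 when per-point standard errors are given, else the fit
    is unweighted.
    """
    est = HillRegressor(fix_h=fix_h).fit(doses, responses, se=errors)
    return est.params_, est.se_
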