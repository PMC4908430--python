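"""Hill analysis of the Mg2+ dependence of self-cleavage rate constants.

The observed rate follows k_obs = k_max * [Mg]^n / (K_half^n + [Mg]^n).
Two estimators of the Hill coefficient n are provided:

* ``fit_loglog_slope`` — ordinary least squares on log k_obs vs log [Mg],
  valid when the titration stays far below K_half (the slope of the Hill
  curve tends to n as [Mg]/K_half -> 0);
* ``fit_hill_nonlinear`` — the full Hill model, fitted in log space with
  the identifiable parameterization log k = log c + n log m - log(1 +
  (m/K)^n), where c = k_max / K_half^n is the lumped sub-saturation scale.
  When the data never approach saturation, c and n remain well determined
  even though k_max and K_half individually are not; the returned
  ``saturation_flag`` records whether K_half fell inside the measured
  concentration range.

Concentrations are in mM, rates in s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, SaturationWarning, ValidationError

__all__ = ["MgTitration", "HillFit", "fit_loglog_slope", "fit_hill_nonlinear"]


@dataclass(frozen=True)
class MgTitration:
    """Paired Mg2+ concentrations (mM, strictly increasing) and k_obs (s^-1)."""

    mg_mM: np.ndarray
    k_obs: np.ndarray
    construct_id: str = ""

    def __post_init__(self):
        m = np.asarray(self.mg_mM, dtype=float)
        k = np.asarray(self.k_obs, dtype=float)
        object.__setattr__(self, "mg_mM", m)
        object.__setattr__(self, "k_obs", k)
        if m.ndim != 1 or k.ndim != 1 or len(m) != len(k):
            raise ValidationError("mg_mM and k_obs must be equal-length 1-D")
        if len(m) < 3:
            raise InsufficientDataError("need >= 3 titration points")
        if np.any(m <= 0) or np.any(k <= 0):
            raise ValidationError("concentrations and rates must be positive")
        if np.any(np.diff(m) <= 0):
            raise ValidationError("mg_mM must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mg_mM)


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-coefficient estimate.

    ``k_max`` and ``K_half`` are ``None`` for the log-log method, and are
    only meaningfully constrained by the nonlinear method when
    ``saturation_flag`` is True.
    """

    n: float
    method: Literal["loglog", "nonlinear"]
    k_max: float | None = None
    K_half: float | None = None
    saturation_flag: bool = False
    intercept: float | None = None
    r_squared: float | None = None
    rss: float | None = None

    def predict(self, mg_mM) -> np.ndarray:
        m = np.asarray(mg_mM, dtype=float)
        if self.method == "loglog":
            return 10 ** (self.intercept + self.n * np.log10(m))
        return self.k_max * m ** self.n / (self.K_half ** self.n + m ** self.n)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "k_max_per_s": self.k_max,
            "K_half_mM": self.K_half,
            "saturation_flag": self.saturation_flag,
            "r_squared": self.r_squared,
        }


def _loglog_ols(tit: MgTitration):
    res = stats.linregress(np.log10(tit.mg_mM), np.log10(tit.k_obs))
    return res.slope, res.intercept, res.rvalue ** 2


def fit_loglog_slope(tit: MgTitration, *, check_saturation: bool = True) -> HillFit:
    """Hill coefficient as the OLS slope of log k_obs vs log [Mg2+].

    Emits :class:`SaturationWarning` (never an error) when a quick Hill fit
    places K_half within a decade of the highest tested concentration, the
    regime where this slope systematically underestimates n.
    """
    slope, intercept, r2 = _loglog_ols(tit)
    if check_saturation:
        try:
            nl = fit_hill_nonlinear(tit)
        except FitError:
            nl = None
        if nl is not None and nl.K_half is not None and (
            tit.mg_mM[-1] >= nl.K_half / 10.0
        ):
            warnings.warn(
                f"max [Mg2+] = {tit.mg_mM[-1]:g} mM is within a decade of the "
                f"estimated K_half = {nl.K_half:.3g} mM; log-log slope "
                f"({slope:.3g}) underestimates the Hill coefficient",
                SaturationWarning,
                stacklevel=2,
            )
    return HillFit(n=float(slope), method="loglog", intercept=float(intercept),
                   r_squared=float(r2))


def fit_hill_nonlinear(
    tit: MgTitration,
    fix_n: float | None = None,
    *,
    n_starts: int = 6,
) -> HillFit:
    """Nonlinear Hill fit, least squares on log k_obs.

    Internally parameterized as (log10 c, n, log10 K_half) with
    c = k_max/K_half^n, so the sub-saturation scale and the Hill
    coefficient stay identifiable when saturation was not observed
    (K_half far above the titrated range).  Multi-start over K_half.
    ``fix_n`` pins the Hill coefficient and fits only the scale terms.
    """
    m, k = tit.mg_mM, tit.k_obs
    logm, logk = np.log10(m), np.log10(k)
    slope0, inter0, _ = _loglog_ols(tit)
    n0 = float(np.clip(slope0, 0.05, 10.0))

    logK_starts = np.log10(m[-1]) + np.linspace(-1.0, 4.0, n_starts)

    best = None
    for logK0 in logK_starts:
        if fix_n is None:
            def resid(x):
                logc, n, logK = x
                return logc + n * logm - np.log10(1.0 + (m / 10 ** logK) ** n) - logk
            x0 = [inter0, n0, logK0]
            lb = [-30.0, 1e-3, np.log10(m[0]) - 1.0]
            ub = [30.0, 10.0, np.log10(m[-1]) + 8.0]
        else:
            def resid(x):
                logc, logK = x
                return (
                    logc + fix_n * logm
                    - np.log10(1.0 + (m / 10 ** logK) ** fix_n) - logk
                )
            x0 = [inter0, logK0]
            lb = [-30.0, np.log10(m[0]) - 1.0]
            ub = [30.0, np.log10(m[-1]) + 8.0]
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10000)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        raise FitError("nonlinear Hill fit did not converge from any start")

    if fix_n is None:
        logc, n, logK = best.x
    else:
        (logc, logK), n = best.x, fix_n
    K_half = float(10 ** logK)
    k_max = float(10 ** logc * K_half ** n)
    resid = best.fun
    ss_tot = float(np.sum((logk - logk.mean()) ** 2))
    r2 = 1.0 - float(2 * best.cost) / ss_tot if ss_tot > 0 else 1.0
    return HillFit(
        n=float(n),
        method="nonlinear",
        k_max=k_max,
        K_half=K_half,
        saturation_flag=bool(m[-1] >= K_half),
        r_squared=r2,
        rss=float(2 * best.cost),
    )
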