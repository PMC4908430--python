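"""Energy-coupling regressions: how P1.2 stability buys activation energy.

Three related analyses of a construct panel:

* ``linear_coupling_fit`` — OLS of apparent activation energy on P1.2
  stability.  The reported ``slope`` is dE_a/ddG (positive: a more
  negative, i.e. more stable, dG gives a lower barrier), the convention
  in which the coupling fraction is ~0.38 — about a third of the helix
  folding energy transduced into barrier lowering.
* ``hinge_fit`` — a continuous linear-then-flat segmented model that
  captures the leveling-off once the helix contributes more than ~4
  kcal/mol: beyond that, the conformational step is no longer
  rate-limiting and extra stability buys nothing.
* ``info_activity_fit`` — log-linear fit of k_obs against helix
  information content (2 bits/bp), summarized as the fold-change in rate
  per 10 additional bits.

Internally the regressions run on the stability-contribution magnitude
x = -dG (kcal/mol, >= 0), which makes the hinge breakpoint directly
comparable to the ~4 kcal/mol plateau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energetics import Condition
from .errors import GroupingError, InsufficientDataError, ValidationError
from .kinetics import aicc

__all__ = [
    "ConstructRecord",
    "CouplingFit",
    "InfoActivityFit",
    "linear_coupling_fit",
    "hinge_fit",
    "info_activity_fit",
]


@dataclass
class ConstructRecord:
    """One ribozyme variant: helix descriptors, condition and measured rate.

    ``stability`` is the signed folding free energy dG37 of the P1.2
    contribution (kcal/mol, <= 0 for a stabilizing helix).
    """

    construct_id: str
    k_obs: float
    stability: float | None = None
    p12_bp: int | None = None
    p12_bits: float | None = None
    linker_class: str = ""
    condition: Condition = field(default_factory=Condition)
    E_a_apparent: float | None = None
    is_wildtype: bool = False

    def __post_init__(self):
        if self.k_obs is not None and self.k_obs <= 0:
            raise ValidationError(
                f"{self.construct_id}: k_obs must be positive, got {self.k_obs}"
            )
        if (
            self.p12_bp is not None
            and self.p12_bits is not None
            and abs(self.p12_bits - 2.0 * self.p12_bp) > 1e-9
        ):
            raise ValidationError(
                f"{self.construct_id}: p12_bits ({self.p12_bits}) != "
                f"2 * p12_bp ({self.p12_bp})"
            )


@dataclass(frozen=True)
class CouplingFit:
    """A fitted E_a-vs-stability relationship.

    ``slope`` is dE_a/ddG (the positive literature convention);
    ``slope_vs_magnitude = -slope`` is the slope against x = -dG.
    ``breakpoint`` (magnitude scale, kcal/mol) is set only when the hinge
    model was selected.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    rss: float
    group: str = "pooled"
    model: str = "linear"
    breakpoint: float | None = None

    @property
    def slope_vs_magnitude(self) -> float:
        return -self.slope

    def predict_Ea(self, stability) -> np.ndarray:
        """Predicted E_a at signed dG values."""
        x = -np.asarray(stability, dtype=float)
        if self.breakpoint is not None:
            x = np.minimum(x, self.breakpoint)
        return self.intercept + self.slope_vs_magnitude * x

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "model": self.model,
            "slope_dEa_ddG": self.slope,
            "slope_vs_magnitude": self.slope_vs_magnitude,
            "intercept_kcal": self.intercept,
            "breakpoint_kcal": self.breakpoint,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "rss": self.rss,
        }


@dataclass(frozen=True)
class InfoActivityFit:
    """Log-linear information-activity relationship."""

    fold_per_10bits: float
    slope_log10k_per_bit: float
    intercept_log10k: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "fold_per_10bits": self.fold_per_10bits,
            "slope_log10k_per_bit": self.slope_log10k_per_bit,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def _ols(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS: slope, intercept, rss, r^2."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValidationError("regressor is constant (rank-deficient fit)")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid ** 2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else 1.0
    return slope, intercept, rss, r2


def _prepare(records, exclude_wildtype: bool):
    recs = [r for r in records if not (exclude_wildtype and r.is_wildtype)]
    for r in recs:
        if r.stability is None or r.E_a_apparent is None:
            raise ValidationError(
                f"{r.construct_id}: stability and E_a_apparent are required "
                "(run the energetics stage first)"
            )
    x = np.array([-r.stability for r in recs], dtype=float)  # magnitude
    y = np.array([r.E_a_apparent for r in recs], dtype=float)
    return recs, x, y


def _check_uniform_condition(recs, group: str) -> None:
    conds = {r.condition for r in recs}
    if len(conds) > 1:
        raise GroupingError(
            f"group {group!r} mixes {len(conds)} conditions; "
            "fit per condition or pool explicitly"
        )


def linear_coupling_fit(
    records,
    group_by_linker: bool = False,
    exclude_wildtype: bool = True,
):
    """OLS of apparent activation energy versus P1.2 stability.

    Returns one :class:`CouplingFit` for the pooled panel, or a dict
    ``{linker_class: CouplingFit}`` with ``group_by_linker`` — the panel
    is only expected to be linear within a family of constructs sharing
    the same connecting linkers.  Grouped fits require a uniform
    condition per group; the pooled fit only warns on mixed conditions.
    """
    if group_by_linker:
        groups: dict[str, list] = {}
        for r in records:
            groups.setdefault(r.linker_class, []).append(r)
        out = {}
        for name, recs in groups.items():
            _check_uniform_condition(recs, name)
            fit = linear_coupling_fit(recs, False, exclude_wildtype)
            out[name] = CouplingFit(**{**fit.__dict__, "group": name or "unlabeled"})
        return out

    recs, x, y = _prepare(records, exclude_wildtype)
    if len(recs) < 3:
        raise InsufficientDataError("need >= 3 constructs for a coupling fit")
    if len({r.condition for r in recs}) > 1:
        warnings.warn(
            "pooled coupling fit mixes solution conditions", stacklevel=2
        )
    slope_mag, intercept, rss, r2 = _ols(x, y)
    return CouplingFit(
        slope=-slope_mag,
        intercept=intercept,
        r_squared=r2,
        n_points=len(recs),
        rss=rss,
    )


def _hinge_design(x: np.ndarray, bp: float) -> np.ndarray:
    return np.minimum(x, bp)


def hinge_fit(
    records,
    grid_step: float = 0.1,
    exclude_wildtype: bool = True,
) -> CouplingFit:
    """Continuous linear-then-flat fit of E_a versus stability magnitude.

    The breakpoint is profiled over a grid (``grid_step`` kcal/mol) across
    the observed stability range, minimizing total RSS; the hinge is kept
    only when it improves corrected AIC over the plain line (parameter
    counts 3 vs 2), otherwise the linear fit is returned with a warning
    when the data could not span a candidate breakpoint.
    """
    recs, x, y = _prepare(records, exclude_wildtype)
    n = len(recs)
    if n < 3:
        raise InsufficientDataError("need >= 3 constructs")
    lin_slope, lin_int, lin_rss, lin_r2 = _ols(x, y)
    linear = CouplingFit(
        slope=-lin_slope, intercept=lin_int, r_squared=lin_r2,
        n_points=n, rss=lin_rss, model="linear",
    )
    if n < 5 or np.ptp(x) < 2 * grid_step:
        warnings.warn(
            "too few points or too little stability span for a hinge; "
            "returning the linear fit",
            stacklevel=2,
        )
        return linear

    lo, hi = x.min() + grid_step, x.max() - grid_step
    best = None
    for bp in np.arange(lo, hi + grid_step / 2, grid_step):
        z = _hinge_design(x, bp)
        try:
            s, b0, rss, r2 = _ols(z, y)
        except ValidationError:
            continue
        if best is None or rss < best[2]:
            best = (s, b0, rss, r2, bp)
    if best is None:
        return linear
    s, b0, rss, r2, bp = best
    sst = float(np.sum((y - y.mean()) ** 2))
    hinge = CouplingFit(
        slope=-s, intercept=b0,
        r_squared=1.0 - rss / sst if sst > 0 else 1.0,
        n_points=n, rss=rss, model="hinge", breakpoint=float(bp),
    )
    return hinge if aicc(rss, n, 3) < aicc(lin_rss, n, 2) else linear


def info_activity_fit(records, exclude_wildtype: bool = True) -> InfoActivityFit:
    """OLS of log10 k_obs versus helix information content (bits).

    The headline number is 10**(10*slope): the fold-change in rate per 10
    additional bits, i.e. per 5 extra base pairs.
    """
    recs = [r for r in records if not (exclude_wildtype and r.is_wildtype)]
    for r in recs:
        if r.p12_bits is None:
            raise ValidationError(f"{r.construct_id}: p12_bits is required")
        if r.k_obs <= 0:
            raise ValidationError(f"{r.construct_id}: k_obs must be positive")
    if len(recs) < 3:
        raise InsufficientDataError("need >= 3 constructs")
    bits = np.array([r.p12_bits for r in recs], dtype=float)
    logk = np.log10([r.k_obs for r in recs])
    if np.ptp(bits) == 0:
        raise ValidationError("all records have identical information content")
    slope, intercept, rss, r2 = _ols(bits, logk)
    return InfoActivityFit(
        fold_per_10bits=float(10 ** (10 * slope)),
        slope_log10k_per_bit=slope,
        intercept_log10k=intercept,
        r_squared=r2,
        n_points=len(recs),
    )
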