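"""Synthetic-data generators for every input the analysis consumes.

The generators emulate the statistical structure of gel-quantified
self-cleavage assays: fraction-intact time courses with additive
densitometry-like noise and a persistent uncleaved fraction, Mg2+
titrations that stay below saturation, and ladders of constructs whose
P1.2 helix grows one base pair at a time.  Each generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .coupling import ConstructRecord
from .energetics import Condition
from .errors import ValidationError
from .helix_thermo import info_bits
from .kinetics import TimeCourse
from .mg_hill import MgTitration
from .pinch_model import PinchParams, effective_kobs

__all__ = [
    "NoiseSpec",
    "gen_timecourse",
    "gen_timecourse_replicates",
    "gen_titration",
    "gen_construct_ladder",
]

logger = logging.getLogger(__name__)

#: Mean P1.2 stack magnitude used when only a base-pair count is known,
#: kcal/mol per bp (typical mixed-sequence RNA stack).
DEFAULT_MEAN_STACK = 0.81


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: additive Gaussian on fractions (gel densitometry) or
    multiplicative log-normal on rates (between-replicate scatter)."""

    kind: Literal["gaussian_additive", "lognormal_multiplicative"] = "gaussian_additive"
    sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if self.sd > 0 and self.seed is None:
            raise ValidationError("a seed is required when sd > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_timecourse(
    k_list: Sequence[float],
    amp_list: Sequence[float],
    plateau: float,
    times: Sequence[float],
    noise: NoiseSpec | None = None,
    construct_id: str = "synthetic",
    condition_id: str = "",
) -> TimeCourse:
    """Noisy multi-exponential decay sampled at ``times`` (seconds).

    f(t) = plateau + sum_i A_i exp(-k_i t), additive Gaussian noise,
    clipped to [0, 1] with any clipping logged.
    """
    k = np.asarray(k_list, dtype=float)
    a = np.asarray(amp_list, dtype=float)
    if len(k) != len(a):
        raise ValidationError("k_list and amp_list must have equal length")
    if np.any(a < 0) or plateau < 0 or a.sum() + plateau > 1.0 + 1e-9:
        raise ValidationError(
            f"invalid mixture: amplitudes {a.tolist()} + plateau {plateau} "
            "must be non-negative and sum to <= 1"
        )
    t = np.asarray(times, dtype=float)
    f = plateau + np.sum(a[:, None] * np.exp(-np.outer(k, t)), axis=0)
    if noise is not None and noise.sd > 0:
        if noise.kind != "gaussian_additive":
            raise ValidationError("time-course noise must be gaussian_additive")
        f = f + noise.rng().normal(0.0, noise.sd, size=len(t))
    clipped = np.count_nonzero((f < 0) | (f > 1))
    if clipped:
        logger.info(
            "%s: clipped %d/%d noisy fractions into [0, 1]",
            construct_id, clipped, len(t),
        )
    f = np.clip(f, 0.0, 1.0)
    return TimeCourse(
        construct_id=construct_id,
        times=t,
        fraction_intact=f,
        condition_id=condition_id,
    )


def gen_timecourse_replicates(
    k_list: Sequence[float],
    amp_list: Sequence[float],
    plateau: float,
    times: Sequence[float],
    noise: NoiseSpec,
    n_replicates: int = 2,
    construct_id: str = "synthetic",
    condition_id: str = "",
) -> list:
    """Independent noisy replicates of one decay (default 2, the usual
    minimum for a reported rate constant).

    Replicate seeds are spawned deterministically from ``noise.seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if noise.sd > 0 and noise.seed is None:
        raise ValidationError("a seed is required for noisy replicates")
    seeds = np.random.SeedSequence(noise.seed).generate_state(n_replicates)
    return [
        gen_timecourse(
            k_list, amp_list, plateau, times,
            NoiseSpec(kind=noise.kind, sd=noise.sd, seed=int(s % 2**31)),
            construct_id=f"{construct_id}:rep{i + 1}",
            condition_id=condition_id,
        )
        for i, s in enumerate(seeds)
    ]


def gen_titration(
    n_true: float,
    K_half: float,
    k_max: float,
    mg_grid: Sequence[float],
    noise: NoiseSpec | None = None,
    construct_id: str = "synthetic",
) -> MgTitration:
    """Hill-model Mg2+ titration k = k_max m^n / (K^n + m^n), optional
    multiplicative log-normal noise on the rates."""
    m = np.asarray(mg_grid, dtype=float)
    if np.any(m <= 0) or np.any(np.diff(m) <= 0):
        raise ValidationError("mg_grid must be positive and strictly increasing")
    if K_half <= 0 or k_max <= 0 or n_true <= 0:
        raise ValidationError("Hill parameters must be positive")
    k = k_max * m ** n_true / (K_half ** n_true + m ** n_true)
    if noise is not None and noise.sd > 0:
        if noise.kind != "lognormal_multiplicative":
            raise ValidationError("titration noise must be lognormal_multiplicative")
        k = k * np.exp(noise.rng().normal(0.0, noise.sd, size=len(m)))
    return MgTitration(mg_mM=m, k_obs=k, construct_id=construct_id)


def gen_construct_ladder(
    bp_range: Sequence[int],
    mean_stack_dG: float = DEFAULT_MEAN_STACK,
    pinch: PinchParams | None = None,
    noise: NoiseSpec | None = None,
    condition: Condition | None = None,
    linker_class: str = "ladder",
) -> list:
    """Construct ladder with P1.2 length varied over ``bp_range``.

    Stability magnitude = bp * mean_stack_dG (kcal/mol per bp, magnitude
    convention); k_obs comes from the pinch model; information content is
    2 bits per bp.
    """
    if pinch is None:
        pinch = PinchParams()
    bp = list(bp_range)
    if any((b < 0 or int(b) != b) for b in bp):
        raise ValidationError("bp_range must be non-negative integers")
    if mean_stack_dG < 0:
        raise ValidationError("mean_stack_dG is a magnitude (kcal/mol per bp)")
    if condition is None:
        condition = Condition(temperature=pinch.temperature)
    E = np.array([b * mean_stack_dG for b in bp], dtype=float)
    k = np.atleast_1d(effective_kobs(pinch, E))
    if noise is not None and noise.sd > 0:
        if noise.kind != "lognormal_multiplicative":
            raise ValidationError("ladder noise must be lognormal_multiplicative")
        k = k * np.exp(noise.rng().normal(0.0, noise.sd, size=len(k)))
    return [
        ConstructRecord(
            construct_id=f"{linker_class}-p12x{b:02d}",
            k_obs=float(k[i]),
            stability=float(-E[i]),
            p12_bp=int(b),
            p12_bits=info_bits(int(b)),
            linker_class=linker_class,
            condition=condition,
        )
        for i, b in enumerate(bp)
    ]
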