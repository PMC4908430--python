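"""Apparent activation energies relative to the uncatalyzed baseline.

Catalytic proficiency is expressed on an energy scale by comparing the
observed self-cleavage rate constant with the background rate of
phosphodiester transesterification under matched solution conditions:

    E_a(apparent) = -R T ln(k_obs / k_uncat)        [kcal/mol]

The baseline k_uncat comes either from a single configured constant or
from an empirical rate law (first-order in hydroxide in the
base-catalyzed regime, Arrhenius in temperature, linear Mg2+
acceleration) whose coefficients live in a bundled, editable YAML file.
Every regression downstream of this module uses *differences* of E_a
across constructs at a fixed condition, so the absolute baseline — the
least certain number here — cancels; only condition-to-condition
comparisons depend on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Literal

import yaml

from .constants import CAL_TO_J, R_KCAL, rt
from .errors import ConfigError, ValidationError

__all__ = [
    "Condition",
    "UncatModel",
    "EnergyLedger",
    "eval_k_uncat",
    "apparent_Ea",
    "kcal_to_kJ",
    "load_uncat_model",
]


@dataclass(frozen=True)
class Condition:
    """Solution condition of a self-cleavage assay.

    Defaults are the physiological-like reference: 37 °C, pH 7.5, 150 mM
    total monovalent (K+ plus Na+), 1 mM Mg2+.
    """

    temperature: float = 310.15  # K
    pH: float = 7.5
    monovalent_mM: float = 150.0
    mg_mM: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (Kelvin)")
        if self.mg_mM < 0 or self.monovalent_mM < 0:
            raise ValidationError("ion concentrations must be non-negative")

    def label(self) -> str:
        return (
            f"{self.temperature:g}K_pH{self.pH:g}_"
            f"{self.monovalent_mM:g}mM-monovalent_{self.mg_mM:g}mM-Mg"
        )


@dataclass(frozen=True)
class UncatModel:
    """Baseline (uncatalyzed) cleavage-rate model.

    ``constant`` mode returns ``k_ref`` for every condition.
    ``parameterized`` mode scales ``k_ref`` from the reference condition
    using the coefficient table:

    * ``pH_slope`` — decades of rate per pH unit (1.0 = first-order in OH-);
    * ``Ea_uncat_kcal`` — Arrhenius activation energy of the background
      reaction;
    * ``mg_linear_per_mM`` — fractional acceleration per mM Mg2+
      (factor 1 + coeff * mg);
    * ``monovalent_exponent`` — power-law dependence on total monovalent.
    """

    mode: Literal["constant", "parameterized"] = "constant"
    k_ref: float = 2e-10  # s^-1 at the reference condition
    ref_condition: Condition = field(default_factory=Condition)
    coefficients: dict = field(default_factory=dict)
    provenance: str = "unspecified"

    def __post_init__(self):
        if self.k_ref <= 0:
            raise ConfigError("k_ref must be positive")
        if self.mode == "parameterized":
            missing = {
                "pH_slope", "Ea_uncat_kcal", "mg_linear_per_mM",
                "monovalent_exponent",
            } - set(self.coefficients)
            if missing:
                raise ConfigError(
                    f"parameterized baseline missing coefficients: {sorted(missing)}"
                )


def eval_k_uncat(model: UncatModel, cond: Condition) -> float:
    """Baseline cleavage rate (s^-1) at ``cond`` under ``model``."""
    if model.mode == "constant":
        return model.k_ref
    c = model.coefficients
    ref = model.ref_condition
    log10k = math.log10(model.k_ref)
    log10k += c["pH_slope"] * (cond.pH - ref.pH)
    log10k += (
        -c["Ea_uncat_kcal"] / (R_KCAL * math.log(10))
        * (1.0 / cond.temperature - 1.0 / ref.temperature)
    )
    k = 10 ** log10k
    k *= (1.0 + c["mg_linear_per_mM"] * cond.mg_mM) / (
        1.0 + c["mg_linear_per_mM"] * ref.mg_mM
    )
    if c["monovalent_exponent"] != 0.0:
        k *= (cond.monovalent_mM / ref.monovalent_mM) ** c["monovalent_exponent"]
    if k <= 0 or not math.isfinite(k):
        raise ConfigError(f"baseline model evaluated to non-positive rate {k!r}")
    return k


def apparent_Ea(k_obs: float, k_uncat: float, cond: Condition) -> float:
    """Apparent activation energy -R T ln(k_obs/k_uncat) in kcal/mol.

    Negative when the ribozyme is faster than background — i.e. the
    energy-scale expression of its rate enhancement.
    """
    if k_obs <= 0 or k_uncat <= 0:
        raise ValidationError(
            f"rates must be positive (k_obs={k_obs!r}, k_uncat={k_uncat!r})"
        )
    return -rt(cond.temperature) * math.log(k_obs / k_uncat)


def kcal_to_kJ(x: float) -> float:
    """Convert kcal/mol to kJ/mol (thermochemical calorie, x 4.184)."""
    return x * CAL_TO_J


@dataclass(frozen=True)
class EnergyLedger:
    """Per-construct activation-energy bookkeeping entry.

    Stores the exact inputs alongside E_a so the entry is auditable:
    ``E_a_apparent == -R * condition.temperature * ln(k_obs/k_uncat)``.
    """

    construct_id: str
    k_obs: float
    k_uncat: float
    condition: Condition
    E_a_apparent: float
    R: float = R_KCAL
    baseline_mode: str = "constant"

    @classmethod
    def from_rates(
        cls,
        construct_id: str,
        k_obs: float,
        model: UncatModel,
        cond: Condition,
    ) -> "EnergyLedger":
        k_uncat = eval_k_uncat(model, cond)
        return cls(
            construct_id=construct_id,
            k_obs=k_obs,
            k_uncat=k_uncat,
            condition=cond,
            E_a_apparent=apparent_Ea(k_obs, k_uncat, cond),
            baseline_mode=model.mode,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        cond = d.pop("condition")
        d.update({f"condition_{k}": v for k, v in cond.items()})
        return d


def load_uncat_model(path=None) -> UncatModel:
    """Load a baseline model from YAML; defaults to the bundled file."""
    if path is None:
        text = (
            resources.files("ribopinch.data") / "uncat_baseline.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    try:
        ref = Condition(**raw.get("ref_condition", {}))
        return UncatModel(
            mode=raw["mode"],
            k_ref=float(raw["k_ref_per_s"]),
            ref_condition=ref,
            coefficients=raw.get("coefficients", {}),
            provenance=raw.get("provenance", "unspecified"),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid baseline config: {exc}") from exc
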