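"""Arrhenius analysis and transition-state activation thermodynamics.

The slow extraction rate constant k follows k = A exp(-Ea / (R T)), so
ln k is linear in 1/T with slope -Ea/R and intercept ln A. Per-temperature
activation parameters follow from transition-state theory:

    dH* = Ea - R T                        (kJ/mol)
    dS* = R [ln(k h / (kB T)) + dH*/(R T)]  (J/(K mol), Eyring)
    dG* = dH* - T dS*                     (kJ/mol)

The Eyring entropy depends on the unit in which k enters the logarithm;
per-minute is the package default (extraction time courses are sampled in
minutes), with per-second selectable via RunConfig.rate_unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FitError, H_PLANCK, K_BOLTZMANN, R_GAS, RunConfig


@dataclass
class RateSeries:
    """Slow-rate constants of one condition across temperatures.

    Temperatures in Kelvin, rates positive, in `rate_unit` (per_minute by
    default). At least two distinct temperatures are required.
    """

    series_id: str
    temperatures_k: np.ndarray
    k: np.ndarray
    rate_unit: str = "per_minute"

    def __post_init__(self) -> None:
        self.temperatures_k = np.asarray(self.temperatures_k, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if np.unique(self.temperatures_k).size < 2:
            raise FitError("need at least 2 distinct temperatures")
        if np.any(self.k <= 0):
            raise FitError("rate constants must be positive")
        if np.any(self.temperatures_k <= 0):
            raise FitError("temperatures must be positive Kelvin")


@dataclass
class ActivationThermo:
    """Per-temperature transition-state parameters.

    dG is computed from dH and dS, so the identity dG = dH - T dS/1000
    holds exactly by construction.
    """

    temperature_k: float
    dH_kj_mol: float
    dS_j_kmol: float
    dG_kj_mol: float

    @property
    def endothermic(self) -> bool:
        return self.dH_kj_mol > 0

    @property
    def non_spontaneous(self) -> bool:
        return self.dG_kj_mol > 0


class ArrheniusModel:
    """Least-squares Arrhenius fit of ln k on 1/T."""

    def __init__(self, series: RateSeries):
        self.series = series

    def fit(self, two_point: bool = False) -> "ArrheniusResults":
        """Fit; `two_point=True` uses only the extreme temperatures
        (closed form), which some published tables correspond to."""
        T = self.series.temperatures_k
        k = self.series.k
        if two_point:
            i, j = int(np.argmin(T)), int(np.argmax(T))
            slope = (np.log(k[j]) - np.log(k[i])) / (1.0 / T[j] - 1.0 / T[i])
            intercept = np.log(k[i]) - slope / T[i]
            r2 = 1.0
        else:
            x = 1.0 / T
            y = np.log(k)
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        ea = -float(slope) * R_GAS / 1000.0  # kJ/mol
        if ea < 0:
            warnings.warn("negative activation energy (rate decreases with temperature)")
        return ArrheniusResults(self.series, ea, float(intercept), r2)


@dataclass
class ArrheniusResults:
    """Activation energy (kJ/mol), ln of the pre-exponential factor, R^2."""

    series: RateSeries
    ea_kj_mol: float
    ln_a: float
    rsquared: float

    def predict_k(self, temperature_k) -> np.ndarray:
        T = np.asarray(temperature_k, dtype=float)
        return np.exp(self.ln_a - 1000.0 * self.ea_kj_mol / (R_GAS * T))

    def activation_thermo(self, config: RunConfig | None = None) -> list[ActivationThermo]:
        """Transition-state parameters at each temperature of the series."""
        config = config or RunConfig()
        out = []
        for T, k in zip(self.series.temperatures_k, self.series.k):
            dH = activation_enthalpy(self.ea_kj_mol, T)
            k_use = _convert_rate(float(k), self.series.rate_unit, config.rate_unit)
            dS = activation_entropy(k_use, T, dH)
            dG = gibbs_activation(dH, dS, T)
            out.append(ActivationThermo(float(T), dH, dS, dG))
        return out

    def summary(self, config: RunConfig | None = None) -> str:
        lines = [
            f"Arrhenius fit: {self.series.series_id}",
            f"  Ea = {self.ea_kj_mol:.2f} kJ/mol   ln A = {self.ln_a:.3f}"
            f" ({self.series.rate_unit})   R^2 = {self.rsquared:.4f}",
            f"  {'T (K)':>8}{'dH* kJ/mol':>12}{'dS* J/Kmol':>12}{'dG* kJ/mol':>12}",
        ]
        for row in self.activation_thermo(config):
            lines.append(
                f"  {row.temperature_k:8.2f}{row.dH_kj_mol:12.2f}"
                f"{row.dS_j_kmol:12.2f}{row.dG_kj_mol:12.2f}"
            )
        return "\n".join(lines)

    def to_table(self, config: RunConfig | None = None) -> pd.DataFrame:
        rows = self.activation_thermo(config)
        return pd.DataFrame(
            {
                "series_id": self.series.series_id,
                "T_K": [r.temperature_k for r in rows],
                "Ea_kJ_mol": self.ea_kj_mol,
                "dH_kJ_mol": [r.dH_kj_mol for r in rows],
                "dS_J_Kmol": [r.dS_j_kmol for r in rows],
                "dG_kJ_mol": [r.dG_kj_mol for r in rows],
            }
        )


def _convert_rate(k: float, from_unit: str, to_unit: str) -> float:
    if from_unit == to_unit:
        return k
    if (from_unit, to_unit) == ("per_minute", "per_second"):
        return k / 60.0
    if (from_unit, to_unit) == ("per_second", "per_minute"):
        return k * 60.0
    raise ValueError(f"cannot convert rate from {from_unit} to {to_unit}")


def activation_enthalpy(ea_kj_mol: float, temperature_k: float) -> float:
    """dH* = Ea - R T, in kJ/mol."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive Kelvin")
    return ea_kj_mol - R_GAS * temperature_k / 1000.0


def activation_entropy(k: float, temperature_k: float, dh_kj_mol: float) -> float:
    """Eyring activation entropy, J/(K mol).

    `k` must already be expressed in the unit chosen for the Eyring
    logarithm (see module docstring). Doubling k adds exactly R ln 2.
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    T = temperature_k
    return R_GAS * (np.log(k * H_PLANCK / (K_BOLTZMANN * T)) + 1000.0 * dh_kj_mol / (R_GAS * T))


def gibbs_activation(dh_kj_mol: float, ds_j_kmol: float, temperature_k: float) -> float:
    """dG* = dH* - T dS*, in kJ/mol."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive Kelvin")
    return dh_kj_mol - temperature_k * ds_j_kmol / 1000.0
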