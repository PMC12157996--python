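"""Shared domain types, run configuration and exceptions.

Temperatures are accepted in degrees Celsius at the boundary and stored in
Kelvin internally (offset 273.15); rate constants default to per-minute,
matching how extraction time-courses are sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

CELSIUS_OFFSET = 273.15

#: gas constant, J/(mol K)
R_GAS = 8.314
#: Boltzmann constant, J/K (CODATA)
K_BOLTZMANN = 1.380649e-23
#: Planck constant, J s (CODATA)
H_PLANCK = 6.62607e-34

RATE_UNITS = ("per_minute", "per_second")
SS_CONVENTIONS = ("paper_runs", "total_observations")
IC50_SCALES = ("linear", "log")

logger = logging.getLogger("ecx")


class EcxError(Exception):
    """Base class for all package errors."""


class SchemaError(EcxError):
    """A delimited file does not match its declared schema."""


class TableParseError(EcxError):
    """A cell could not be parsed; carries the offending row index."""


class DesignError(EcxError):
    """A factorial dataset is not a complete 2^k design."""


class FitError(EcxError):
    """A model cannot be fitted on the supplied data."""


def celsius_to_kelvin(temp_c: float) -> float:
    if temp_c <= -CELSIUS_OFFSET:
        raise ValueError(f"temperature {temp_c} degC is at or below absolute zero")
    return temp_c + CELSIUS_OFFSET


@dataclass(frozen=True)
class Condition:
    """One extraction condition: solvent strength, temperature, duration.

    Parameters
    ----------
    ethanol_fraction : float
        Ethanol concentration, percent v/v, in [0, 100].
    temperature_c : float
        Extraction temperature in degrees Celsius (> absolute zero).
    duration_min : float, optional
        Extraction time in minutes, >= 0.
    """

    ethanol_fraction: float
    temperature_c: float
    duration_min: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ethanol_fraction <= 100.0:
            raise ValueError(f"ethanol_fraction {self.ethanol_fraction} not in [0, 100]")
        celsius_to_kelvin(self.temperature_c)  # validates
        if self.duration_min is not None and self.duration_min < 0:
            raise ValueError("duration_min must be >= 0")

    @property
    def temperature_k(self) -> float:
        """Temperature in Kelvin (canonical internal unit)."""
        return celsius_to_kelvin(self.temperature_c)

    def label(self) -> str:
        s = f"{self.ethanol_fraction:g}% EtOH, {self.temperature_c:g} degC"
        if self.duration_min is not None:
            s += f", {self.duration_min:g} min"
        return s


@dataclass
class RunConfig:
    """Analysis-wide configuration.

    Attributes
    ----------
    alpha : float
        Significance level for term retention, in (0, 1).
    rate_unit : str
        Unit in which rate constants enter the Eyring relation
        ("per_minute" or "per_second").
    ss_convention : str
        Factorial sum-of-squares convention: "paper_runs" (SS = n_runs * b^2)
        or "total_observations" (SS = N_obs * b^2).
    seed : int
        Non-negative seed; identical seed + inputs give identical outputs.
    ic50_scale : str
        Interpolation scale for IC50 ("log" or "linear").
    """

    alpha: float = 0.05
    rate_unit: str = "per_minute"
    ss_convention: str = "paper_runs"
    seed: int = 0
    ic50_scale: str = "log"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} not in (0, 1)")
        if self.rate_unit not in RATE_UNITS:
            raise ValueError(f"rate_unit must be one of {RATE_UNITS}")
        if self.ss_convention not in SS_CONVENTIONS:
            raise ValueError(f"ss_convention must be one of {SS_CONVENTIONS}")
        if self.ic50_scale not in IC50_SCALES:
            raise ValueError(f"ic50_scale must be one of {IC50_SCALES}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def echo(self) -> str:
        """One-line textual echo, embedded in every written report."""
        return (
            f"alpha={self.alpha} rate_unit={self.rate_unit} "
            f"ss_convention={self.ss_convention} seed={self.seed} "
            f"ic50_scale={self.ic50_scale}"
        )
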