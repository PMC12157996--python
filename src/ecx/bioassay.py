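"""Bioassay summarisation: IC50 interpolation, MIC reduction, correlations.

IC50 is the concentration producing 50 % inhibition, obtained by bracketing
interpolation of the dose-response points (on log concentration by default,
appropriate for geometric dilution ladders). MIC is the lowest concentration
of a two-fold dilution series that inhibits growth. Censoring (activity
never reaching the threshold, or already past it at the lowest tested
concentration) is reported as a typed result, never as a sentinel number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FitError, RunConfig


@dataclass
class DoseResponseCurve:
    """Percent inhibition at strictly increasing concentrations (ug/mL)."""

    sample_id: str
    concentrations: np.ndarray
    inhibition_pct: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition_pct = np.asarray(self.inhibition_pct, dtype=float)
        if self.concentrations.size < 2:
            raise FitError("a dose-response curve needs at least 2 points")
        if np.any(self.concentrations <= 0):
            raise FitError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise FitError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class CensoredValue:
    """Half-maximal or minimum-inhibitory summary, possibly censored.

    `censor` is None for an interior estimate, "gt_max" when activity never
    reaches the threshold within the tested range, "lt_min"/"le_min" when it
    is already reached at the lowest tested concentration.
    """

    value: float
    censor: str | None = None

    @property
    def is_censored(self) -> bool:
        return self.censor is not None

    def __str__(self) -> str:
        prefix = {None: "", "gt_max": "> ", "lt_min": "< ", "le_min": "<= "}[self.censor]
        return f"{prefix}{self.value:g}"


def ic50_from_curve(curve: DoseResponseCurve, config: RunConfig | None = None) -> CensoredValue:
    """IC50 by bracketing interpolation of inhibition vs concentration.

    An exact 50 % reading returns that concentration. With
    ``config.ic50_scale == "log"`` (default) the interpolation is linear in
    log concentration, which is exact for symmetric brackets on geometric
    ladders. No crossing yields a censored result instead of a number.
    """
    config = config or RunConfig()
    c = curve.concentrations
    y = curve.inhibition_pct
    hits = np.nonzero(y == 50.0)[0]
    if hits.size:
        return CensoredValue(float(c[hits[0]]))
    if y[0] > 50.0:
        return CensoredValue(float(c[0]), "lt_min")
    cross = np.nonzero((y[:-1] < 50.0) & (y[1:] > 50.0))[0]
    if cross.size == 0:
        return CensoredValue(float(c[-1]), "gt_max")
    i = int(cross[0])
    frac = (50.0 - y[i]) / (y[i + 1] - y[i])
    if config.ic50_scale == "log":
        lo, hi = np.log(c[i]), np.log(c[i + 1])
        return CensoredValue(float(np.exp(lo + frac * (hi - lo))))
    return CensoredValue(float(c[i] + frac * (c[i + 1] - c[i])))


@dataclass
class DilutionSeries:
    """Two-fold dilution ladder with per-level growth-inhibition flags."""

    strain: str
    concentrations: np.ndarray
    inhibited: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.concentrations, dtype=float))
        self.concentrations = np.asarray(self.concentrations, dtype=float)[order]
        self.inhibited = np.asarray(self.inhibited, dtype=bool)[order]
        if self.concentrations.size < 2:
            raise FitError("a dilution series needs at least 2 levels")
        ratios = self.concentrations[1:] / self.concentrations[:-1]
        if np.any(np.abs(ratios - 2.0) > 0.02):
            raise FitError("concentrations must form a two-fold ladder (within 1 %)")


def mic_from_series(series: DilutionSeries) -> CensoredValue:
    """Minimum inhibitory concentration of a two-fold dilution series.

    Lowest inhibited concentration; all levels inhibited is reported as
    "<= min" (the true MIC may lie below the tested range), none as "> max".
    Row order of the input does not matter (the series is sorted on entry).
    """
    if not series.inhibited.any():
        return CensoredValue(float(series.concentrations[-1]), "gt_max")
    idx = int(np.nonzero(series.inhibited)[0][0])
    if idx == 0 and series.inhibited.all():
        return CensoredValue(float(series.concentrations[0]), "le_min")
    return CensoredValue(float(series.concentrations[idx]))


class ActivityPanel:
    """Condition x assay matrix of IC50 values (ug/mL), all positive."""

    def __init__(self, matrix: pd.DataFrame):
        if matrix.isna().any().any():
            raise FitError("activity panel must be complete (no missing cells)")
        if (matrix.to_numpy(dtype=float) <= 0).any():
            raise FitError("all IC50 values must be positive")
        self.matrix = matrix.astype(float)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ActivityPanel":
        """Build from the long panel schema (condition_id, assay_id, ic50_ug_ml)."""
        wide = df.pivot(index="condition_id", columns="assay_id", values="ic50_ug_ml")
        return cls(wide)

    def pearson_matrix(self, transform: str = "none") -> pd.DataFrame:
        """Pairwise Pearson correlations between assay IC50 columns.

        `transform` may be "none" (IC50 as given), "reciprocal" (1/IC50,
        i.e. a potency scale) or "log". Zero-variance columns yield NaN
        rows/columns with a warning. The result is symmetric with unit
        diagonal and positive semidefinite up to rounding.
        """
        if len(self.matrix) < 3:
            raise FitError("need at least 3 conditions for correlations")
        m = self.matrix
        if transform == "reciprocal":
            m = 1.0 / m
        elif transform == "log":
            m = np.log(m)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        zero_var = m.std(ddof=1) == 0
        if zero_var.any():
            warnings.warn(f"zero-variance column(s): {list(m.columns[zero_var])}; NaN correlations")
        return m.corr(method="pearson")


def pearson_matrix(panel: ActivityPanel, transform: str = "none") -> pd.DataFrame:
    """Functional alias for :meth:`ActivityPanel.pearson_matrix`."""
    return panel.pearson_matrix(transform=transform)
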