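"""Extraction kinetics: unsteady-state diffusion and Ponomarev models.

Both models describe a normalized extraction yield fraction q(t) in [0, 1]
over a washing stage (fast surface dissolution, captured by the washing
coefficient b) followed by a slow diffusion-limited stage (rate constant k,
per minute):

* unsteady-state diffusion:  q(t) = 1 - (1 - b) exp(-k t),
  fitted as the line ln(1 - q) = ln(1 - b) - k t;
* Ponomarev (empirical linear):  q(t) = b' + k' t,
  fitted as a straight line of q on t.

Fits use ordinary least squares on the linearized form; goodness of fit is
reported on the original q scale as R^2 and the mean-relative root-square
percentage RMS = 100 sqrt(mean(((qhat - q)/q)^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import Condition, FitError

UNSTEADY_DIFFUSION = "unsteady_diffusion"
PONOMAREV = "ponomarev"

#: tolerance for the "q non-decreasing" sanity warning
_MONOTONE_TOL = 0.05


@dataclass
class TimeCourse:
    """Normalized extraction yield q versus time (minutes).

    q is the activity-derived yield at time t divided by its equilibrium
    (long-time) value, so q is dimensionless in [0, 1] and expected to be
    roughly non-decreasing.
    """

    times: np.ndarray
    q: np.ndarray
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.size < 3:
            raise FitError("a time course needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise FitError("times must be strictly increasing")
        if np.any((self.q < 0) | (self.q > 1)):
            raise FitError("q must lie in [0, 1]")
        if np.any(np.diff(self.q) < -_MONOTONE_TOL):
            warnings.warn("q decreases by more than 0.05 between points; check normalization")


@dataclass
class KineticResults:
    """Fitted kinetic model with goodness of fit on the original scale."""

    model: str
    washing_coefficient: float
    rate_constant: float  # per minute
    rsquared: float
    rms_percent: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.model == UNSTEADY_DIFFUSION:
            return 1.0 - (1.0 - self.washing_coefficient) * np.exp(-self.rate_constant * t)
        return np.minimum(self.washing_coefficient + self.rate_constant * t, 1.0)

    def summary(self) -> str:
        name = "unsteady-state diffusion" if self.model == UNSTEADY_DIFFUSION else "Ponomarev"
        lines = [
            f"{name} kinetic fit ({self.n_points} points)",
            f"  washing coefficient b  = {self.washing_coefficient:.4g}",
            f"  slow rate constant k   = {self.rate_constant:.4g} / min",
            f"  R^2 = {self.rsquared:.4f}   RMS = {self.rms_percent:.2f} %",
        ]
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)


class _KineticModelBase:
    """Shared scaffolding: window selection, goodness of fit."""

    model_name = ""

    def __init__(self, timecourse: TimeCourse, t_min: float | None = None):
        self.tc = timecourse
        mask = np.ones(self.tc.times.size, dtype=bool)
        if t_min is not None:
            mask &= self.tc.times >= t_min
        self._window = mask

    def _goodness(self, results: KineticResults) -> KineticResults:
        r2, rms = goodness(self.tc, results)
        results.rsquared = r2
        results.rms_percent = rms
        return results


class UnsteadyDiffusionModel(_KineticModelBase):
    """ln(1 - q) regressed on t; slope -k, intercept ln(1 - b)."""

    model_name = UNSTEADY_DIFFUSION

    def fit(self) -> KineticResults:
        t = self.tc.times[self._window]
        q = self.tc.q[self._window]
        usable = q < 1.0
        if not np.all(usable):
            warnings.warn(f"dropping {np.sum(~usable)} point(s) with q >= 1 from log fit")
        t, q = t[usable], q[usable]
        if t.size < 3:
            raise FitError("fewer than 3 usable points for the diffusion fit")
        slope, intercept = np.polyfit(t, np.log(1.0 - q), 1)
        k = -float(slope)
        b = 1.0 - float(np.exp(intercept))
        if abs(k) < 1e-12:  # washing-only limit: slope is numerically zero
            k = 0.0
        flags = []
        if k <= 0:
            warnings.warn("estimated rate constant is non-positive")
            flags.append("non-positive rate constant")
        res = KineticResults(self.model_name, b, k, np.nan, np.nan, t.size, flags)
        return self._goodness(res)


class PonomarevModel(_KineticModelBase):
    """q regressed on t; intercept b', slope k'."""

    model_name = PONOMAREV

    def fit(self) -> KineticResults:
        t = self.tc.times[self._window]
        q = self.tc.q[self._window]
        if t.size < 2:
            raise FitError("fewer than 2 points in the Ponomarev fit window")
        slope, intercept = np.polyfit(t, q, 1)
        flags = []
        if slope <= 0:
            warnings.warn("estimated rate constant is non-positive")
            flags.append("non-positive rate constant")
        res = KineticResults(self.model_name, float(intercept), float(slope), np.nan, np.nan, t.size, flags)
        return self._goodness(res)


MODELS = {UNSTEADY_DIFFUSION: UnsteadyDiffusionModel, PONOMAREV: PonomarevModel}


def fit_kinetics(tc: TimeCourse, model: str, t_min: float | None = None) -> KineticResults:
    """Convenience dispatcher over the two kinetic model classes."""
    try:
        cls = MODELS[model]
    except KeyError:
        raise FitError(f"unknown kinetic model {model!r}; choose from {sorted(MODELS)}")
    return cls(tc, t_min=t_min).fit()


def goodness(tc: TimeCourse, fit: KineticResults) -> tuple[float, float]:
    """R^2 and relative RMS%% of a fitted model on the original q scale.

    R^2 is undefined (NaN, with a warning) when the observed q has zero
    variance; points with q = 0 are excluded from the RMS with a warning.
    """
    qhat = fit.predict(tc.times)
    resid = tc.q - qhat
    ss_tot = float(np.sum((tc.q - tc.q.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("observed q has zero variance; R^2 undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    nonzero = tc.q != 0
    if not np.all(nonzero):
        warnings.warn("excluding q = 0 point(s) from relative RMS")
    if not np.any(nonzero):
        return r2, np.nan
    rel = resid[nonzero] / tc.q[nonzero]
    rms = 100.0 * float(np.sqrt(np.mean(rel**2)))
    return r2, rms


@dataclass
class ModelComparison:
    """Ranking of competing kinetic fits of one time course."""

    ranking: list[KineticResults]
    r2_winner: str
    rms_winner: str
    verdict: str
    tie: bool

    def summary(self) -> str:
        order = " > ".join(f.model for f in self.ranking)
        s = f"ranking: {order}\nR^2 winner: {self.r2_winner}; RMS winner: {self.rms_winner}\n"
        s += f"combined verdict: {self.verdict}" + ("  (tie)" if self.tie else "")
        return s


def compare_models(fits: list[KineticResults]) -> ModelComparison:
    """Rank fits by higher R^2, then lower RMS; report per-criterion winners.

    The order of `fits` breaks exact ties (stable sort), and such ties are
    flagged.
    """
    if len(fits) < 2:
        raise FitError("need at least two fits to compare")
    keyed = sorted(fits, key=lambda f: (-(f.rsquared if np.isfinite(f.rsquared) else -np.inf),
                                        f.rms_percent if np.isfinite(f.rms_percent) else np.inf))
    r2_winner = max(fits, key=lambda f: f.rsquared if np.isfinite(f.rsquared) else -np.inf).model
    rms_winner = min(fits, key=lambda f: f.rms_percent if np.isfinite(f.rms_percent) else np.inf).model
    top = keyed[0]
    tie = any(
        f is not top and f.rsquared == top.rsquared and f.rms_percent == top.rms_percent
        for f in keyed
    )
    return ModelComparison(keyed, r2_winner, rms_winner, top.model, tie)
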