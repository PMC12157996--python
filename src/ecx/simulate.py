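"""Synthetic-data generators emulating every input the pipeline consumes.

Each generator draws from a stated noise model around known ("true")
parameters, so parameter-recovery and model-selection behaviour can be
tested without any external data:

* factorial responses: coded-polynomial mean + Gaussian replicate noise;
* extraction time courses: kinetic-model mean + Gaussian noise on q,
  clipped to [0, 0.999];
* rate-vs-temperature series: Arrhenius mean with multiplicative lognormal
  noise;
* dose-response readings: Hill curve + additive Gaussian noise on percent
  inhibition;
* IC50 panels: a shared latent condition factor with per-assay loadings
  inducing positive cross-assay correlation, plus lognormal noise.

Presets named after the three cell lines of the bundled reference study
("hep2c", "rd", "l2ob") ship its published coefficients and kinetic/
Arrhenius parameters as generating truths.

All generators are deterministic given a seed (or a caller-supplied
Generator); the seed used is logged at debug level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .bioassay import ActivityPanel, DoseResponseCurve
from .config import R_GAS, celsius_to_kelvin, logger
from .doe import FactorialModel, term_names
from .kinetics import PONOMAREV, UNSTEADY_DIFFUSION, TimeCourse
from .thermo import RateSeries


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    logger.debug("simulate: seeding generator with %s", seed_or_rng)
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# specs

@dataclass
class FactorialSpec:
    """True coefficients over the 8 saturated terms + replicate noise."""

    beta: dict[str, float]
    n_replicates: int = 2
    sigma_rep: float = 0.005

    def __post_init__(self) -> None:
        k = int(np.log2(len(self.beta)))
        if 2**k != len(self.beta) or set(self.beta) != set(term_names(k)):
            raise ValueError("beta must map every saturated term of a 2^k model")
        if self.sigma_rep < 0 or self.n_replicates < 1:
            raise ValueError("sigma_rep >= 0 and n_replicates >= 1 required")
        self.k = k


@dataclass
class KineticsSpec:
    """Generating kinetic model and parameters on a fixed time grid."""

    model: str = UNSTEADY_DIFFUSION
    b: float = 0.441
    k: float = 2.46e-3  # per minute
    times: tuple = datasets.TIMECOURSE_MINUTES
    sigma_q: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.b < 1:
            raise ValueError("b must be in [0, 1)")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.sigma_q < 0:
            raise ValueError("sigma_q must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be increasing")


@dataclass
class ArrheniusSpec:
    """True activation energy (kJ/mol) and pre-exponential factor."""

    ea_kj_mol: float = 13.89
    a: float = 0.33  # same unit as the generated k (per minute)
    temperatures_c: tuple = (30.0, 40.0, 50.0)
    sigma_ln: float = 0.02

    def __post_init__(self) -> None:
        if self.ea_kj_mol < 0 or self.a <= 0 or self.sigma_ln < 0:
            raise ValueError("require Ea >= 0, A > 0, sigma_ln >= 0")


@dataclass
class DoseResponseSpec:
    """Hill curve truth on a geometric concentration ladder."""

    ic50: float = 14.29
    hill: float = 1.0
    ladder: tuple = tuple(2.0**i for i in range(1, 9))
    sigma_i: float = 0.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.hill <= 0 or self.sigma_i < 0:
            raise ValueError("require ic50 > 0, hill > 0, sigma_i >= 0")
        ratios = np.diff(np.log(np.asarray(self.ladder)))
        if np.any(ratios <= 0) or np.ptp(ratios) > 1e-9:
            raise ValueError("concentration ladder must be geometric and increasing")


@dataclass
class PanelSpec:
    """Latent-factor panel: IC50 = base * exp(loading * Z + noise)."""

    base_ic50: dict[str, float] = field(
        default_factory=lambda: {a: 15.0 for a in ("LP", "DPPH", "MC", "OH", "ABTS", "Hep2c", "RD", "L2OB")}
    )
    loading: float = 0.3
    n_conditions: int = 9
    sigma_p: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.n_conditions < 3:
            raise ValueError("sigma_p >= 0 and n_conditions >= 3 required")


@dataclass
class SynthSpec:
    """Everything the pipeline consumes, with one master seed."""

    seed: int = 0
    factorial: FactorialSpec = field(
        default_factory=lambda: FactorialSpec(dict(datasets.POLYNOMIAL_COEFFICIENTS["hep2c"]))
    )
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    arrhenius: ArrheniusSpec = field(default_factory=ArrheniusSpec)
    doseresponse: DoseResponseSpec = field(default_factory=DoseResponseSpec)
    panel: PanelSpec = field(default_factory=PanelSpec)


# ---------------------------------------------------------------------------
# generators

def gen_factorial(spec: FactorialSpec, seed=0) -> FactorialModel:
    """Complete 2^k dataset: polynomial mean + N(0, sigma_rep) per replicate."""
    rng = _rng(seed)
    import itertools

    combos = np.array(list(itertools.product((-1.0, 1.0), repeat=spec.k)))
    names = term_names(spec.k)
    means = np.zeros(len(combos))
    for name in names:
        if name == "b0":
            means += spec.beta["b0"]
        else:
            idx = [int(c) - 1 for c in name[1:]]
            means += spec.beta[name] * np.prod(combos[:, idx], axis=1)
    noise = rng.normal(0.0, spec.sigma_rep, size=(len(combos), spec.n_replicates))
    return FactorialModel(combos, means[:, None] + noise)


def kinetic_mean(model: str, times: np.ndarray, b: float, k: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if model == UNSTEADY_DIFFUSION:
        return 1.0 - (1.0 - b) * np.exp(-k * times)
    if model == PONOMAREV:
        return np.minimum(b + k * times, 1.0)
    raise ValueError(f"unknown kinetic model {model!r}")


def gen_timecourse(spec: KineticsSpec, seed=0, condition=None) -> TimeCourse:
    """Noisy time course from the generating model, clipped to [0, 0.999]."""
    rng = _rng(seed)
    times = np.asarray(spec.times, dtype=float)
    q = kinetic_mean(spec.model, times, spec.b, spec.k)
    q = q + rng.normal(0.0, spec.sigma_q, size=times.size)
    return TimeCourse(times, np.clip(q, 0.0, 0.999), condition=condition)


def gen_arrhenius(spec: ArrheniusSpec, seed=0, series_id="synthetic") -> RateSeries:
    """k(T) = A exp(-1000 Ea / (R T)) with multiplicative lognormal noise."""
    rng = _rng(seed)
    T = np.array([celsius_to_kelvin(c) for c in spec.temperatures_c])
    k = spec.a * np.exp(-1000.0 * spec.ea_kj_mol / (R_GAS * T))
    k = k * np.exp(rng.normal(0.0, spec.sigma_ln, size=T.size))
    return RateSeries(series_id, T, k)


def hill_inhibition(conc, ic50: float, hill: float) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    return 100.0 * c**hill / (ic50**hill + c**hill)


def gen_dose_response(spec: DoseResponseSpec, seed=0, sample_id="synthetic") -> DoseResponseCurve:
    """Hill readout with additive Gaussian noise on percent inhibition."""
    rng = _rng(seed)
    c = np.asarray(spec.ladder, dtype=float)
    y = hill_inhibition(c, spec.ic50, spec.hill)
    y = y + rng.normal(0.0, spec.sigma_i, size=c.size)
    return DoseResponseCurve(sample_id, c, y)


def gen_panel(spec: PanelSpec, seed=0) -> ActivityPanel:
    """Cross-correlated IC50 panel via a shared latent condition factor."""
    rng = _rng(seed)
    z = rng.normal(0.0, 1.0, size=spec.n_conditions)
    assays = list(spec.base_ic50)
    data = {}
    for assay in assays:
        eps = rng.normal(0.0, spec.sigma_p, size=spec.n_conditions)
        data[assay] = spec.base_ic50[assay] * np.exp(spec.loading * z + eps)
    idx = [f"cond_{i+1}" for i in range(spec.n_conditions)]
    return ActivityPanel(pd.DataFrame(data, index=idx))


# ---------------------------------------------------------------------------
# presets and CSV emission

def preset(name: str) -> SynthSpec:
    """Generating truths taken from the bundled reference study tables."""
    if name not in datasets.CELL_LINES:
        raise KeyError(f"unknown preset {name!r}; choose from {datasets.CELL_LINES}")
    b30 = datasets.WASHING_COEFFICIENTS[(name, 30)]
    rc = datasets.rate_constants(name)
    k30 = rc.loc[(rc.series_id == f"{name}_30pct") & (rc.temp_C == 30.0), "k"].iloc[0]
    return SynthSpec(
        factorial=FactorialSpec(dict(datasets.POLYNOMIAL_COEFFICIENTS[name])),
        kinetics=KineticsSpec(b=b30, k=float(k30)),
    )


def to_csv_tables(spec: SynthSpec) -> dict[str, pd.DataFrame]:
    """Render one synthetic dataset per input schema, keyed by schema name.

    Deterministic: each table draws from its own child seed derived from
    `spec.seed`, so byte-identical CSVs result from identical specs.
    """
    master = np.random.default_rng(spec.seed)
    seeds = master.integers(0, 2**31 - 1, size=5)

    fm = gen_factorial(spec.factorial, int(seeds[0]))
    # actual levels per the reference design: EtOH 30/70 %, T 30/50 degC,
    # t 20/80 min (mid +/- half-range on the coded axis)
    mids, halves = (50.0, 40.0, 50.0), (20.0, 10.0, 30.0)
    design_rows = []
    for i, row in enumerate(fm.coded):
        actual = [m + h * row[j] for j, (m, h) in enumerate(zip(mids, halves))]
        for rep in range(fm.n_reps):
            design_rows.append((i + 1, *actual, rep + 1, fm.responses[i, rep]))
    design = pd.DataFrame(
        design_rows, columns=["run", "ethanol_pct", "temp_C", "time_min", "replicate", "response"]
    )

    tc = gen_timecourse(spec.kinetics, int(seeds[1]))
    timecourse = pd.DataFrame(
        {"ethanol_pct": 30.0, "temp_C": 30.0, "time_min": tc.times, "response": tc.q}
    )

    rs = gen_arrhenius(spec.arrhenius, int(seeds[2]))
    rates = pd.DataFrame(
        {"series_id": rs.series_id, "temp_C": rs.temperatures_k - 273.15, "k": rs.k}
    )

    dr = gen_dose_response(spec.doseresponse, int(seeds[3]))
    doseresponse = pd.DataFrame(
        {
            "sample_id": dr.sample_id,
            "concentration_ug_ml": dr.concentrations,
            "inhibition_pct": dr.inhibition_pct,
        }
    )

    panel = gen_panel(spec.panel, int(seeds[4]))
    long = panel.matrix.reset_index(names="condition_id").melt(
        id_vars="condition_id", var_name="assay_id", value_name="ic50_ug_ml"
    )

    return {
        "design": design,
        "timecourse": timecourse,
        "rates": rates,
        "doseresponse": doseresponse,
        "panel": long,
    }
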