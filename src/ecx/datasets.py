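"""Bundled reference measurements from a 2^3 maceration study of spring
heath (Erica carnea L.) aerial parts.

The study varied ethanol concentration (30/70 % v/v), temperature
(30/50 degC) and time (20/80 min) and recorded a normalized yield of
cytotoxic activity against three cell lines (Hep2c, RD, L2OB), together
with extraction-kinetics parameters at 30/40/50 degC for three ethanol
strengths, transition-state parameters, and IC50 panels for cytotoxic and
antioxidant assays. No machine-readable deposit exists; the published
summary tables below are the study's only available data and serve as
reference inputs and example datasets throughout the package.

Caveats carried by the source tables (also noted where relevant in the
API docs): the published run means reproduce only some of the published
regression coefficients, and only run means (not replicates) are printed,
so the published replicate error sums of squares are provided separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doe import FactorDef

CELL_LINES = ("hep2c", "rd", "l2ob")

#: actual low/high levels of the three factors
FACTORS = [
    FactorDef("ethanol_pct", 30.0, 70.0),
    FactorDef("temp_C", 30.0, 50.0),
    FactorDef("time_min", 20.0, 80.0),
]

# 8 runs x (ethanol %, temp C, time min) in standard order, plus mean yield
# of cytotoxic activity per cell line
_DESIGN_ROWS = [
    # run, EtOH, T, t,  hep2c,  rd,    l2ob
    (1, 30, 30, 20, 0.454, 0.558, 0.328),
    (2, 70, 30, 20, 0.442, 0.421, 0.181),
    (3, 30, 50, 20, 0.465, 0.570, 0.328),
    (4, 70, 50, 20, 0.450, 0.439, 0.192),
    (5, 30, 30, 80, 0.669, 0.692, 0.586),
    (6, 70, 30, 80, 0.606, 0.602, 0.391),
    (7, 30, 50, 80, 0.683, 0.716, 0.603),
    (8, 70, 50, 80, 0.659, 0.647, 0.448),
]

#: published saturated-model coefficients per cell line
POLYNOMIAL_COEFFICIENTS = {
    "hep2c": {
        "b0": 0.5535, "b1": -0.0142, "b2": 0.0087, "b3": 0.1007,
        "b12": 0.0025, "b13": -0.0075, "b23": 0.0080, "b123": 0.0072,
    },
    "rd": {
        "b0": 0.5806, "b1": -0.0534, "b2": 0.0124, "b3": 0.0836,
        "b12": 0.0034, "b13": 0.0136, "b23": 0.0049, "b123": 0.0019,
    },
    "l2ob": {
        "b0": 0.3792, "b1": -0.0762, "b2": 0.0135, "b3": 0.1277,
        "b12": 0.0035, "b13": 0.0112, "b23": 0.0050, "b123": 0.0065,
    },
}

#: published pure-error sum of squares and df (replicates were not printed)
ERROR_SS = {"hep2c": (0.00016, 8), "rd": (0.00032, 8), "l2ob": (0.00048, 8)}

# slow-rate constants k (per minute) of the unsteady-state diffusion model,
# per cell line / ethanol % / temperature (30, 40, 50 degC)
_RATE_ROWS = [
    ("hep2c", 30, [2.46e-3, 2.64e-3, 2.87e-3]),
    ("hep2c", 50, [1.33e-3, 1.60e-3, 1.87e-3]),
    ("hep2c", 70, [1.76e-3, 1.90e-3, 2.28e-3]),
    ("rd", 30, [2.08e-3, 2.24e-3, 2.79e-3]),
    ("rd", 50, [1.42e-3, 1.58e-3, 1.78e-3]),
    ("rd", 70, [1.91e-3, 2.08e-3, 2.18e-3]),
    ("l2ob", 30, [3.27e-3, 3.48e-3, 3.69e-3]),
    ("l2ob", 50, [2.11e-3, 2.45e-3, 2.69e-3]),
    ("l2ob", 70, [1.74e-3, 2.17e-3, 2.67e-3]),
]

#: washing coefficients b of the diffusion model at 30 degC, per series
WASHING_COEFFICIENTS = {
    ("hep2c", 30): 0.441, ("hep2c", 50): 0.352, ("hep2c", 70): 0.414,
    ("rd", 30): 0.613, ("rd", 50): 0.374, ("rd", 70): 0.386,
    ("l2ob", 30): 0.255, ("l2ob", 50): 0.089, ("l2ob", 70): 0.154,
}

#: Ponomarev parameters (b', k' per minute) at 30 degC for one reference series
PONOMAREV_REFERENCE = {("hep2c", 30): (0.450, 2.35e-3)}

# IC50 (ug/mL) of the nine extraction conditions (ethanol % x temperature)
# across five antioxidant assays and three cytotoxicity assays
_PANEL_COLUMNS = ("LP", "DPPH", "MC", "OH", "ABTS", "Hep2c", "RD", "L2OB")
_PANEL_ROWS = [
    ("30pct_30C", 21.44, 19.35, 8.76, 13.54, 13.08, 16.33, 15.70, 25.21),
    ("30pct_40C", 20.01, 18.45, 7.66, 13.21, 12.61, 15.23, 14.19, 24.26),
    ("30pct_50C", 19.44, 16.55, 6.98, 13.09, 12.17, 14.29, 13.93, 22.23),
    ("50pct_30C", 27.60, 25.03, 16.01, 19.42, 17.41, 24.37, 22.44, 31.91),
    ("50pct_40C", 26.42, 24.43, 13.48, 17.19, 17.13, 23.38, 21.40, 30.48),
    ("50pct_50C", 25.25, 23.98, 12.45, 16.92, 16.83, 20.55, 17.49, 28.32),
    ("70pct_30C", 24.77, 22.14, 11.45, 14.22, 16.06, 22.22, 18.53, 29.55),
    ("70pct_40C", 24.23, 21.09, 10.98, 14.02, 15.51, 21.36, 17.88, 28.87),
    ("70pct_50C", 22.54, 20.94, 10.52, 13.97, 14.21, 20.24, 17.19, 27.88),
]

#: sampling times (minutes) used for the extraction time courses
TIMECOURSE_MINUTES = (10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0)

#: two-fold dilution ladder (ug/mL) of the broth microdilution assay,
#: spanning the reported 19.53-625 range
DILUTION_LADDER = tuple(625.0 / 2**i for i in range(5, -1, -1))


def factorial_design(response: str | None = None) -> pd.DataFrame:
    """The 8-run design with actual levels and mean responses.

    With `response` in {"hep2c", "rd", "l2ob"} the frame matches the
    `design` schema (single replicate of run means); without it all three
    response columns are kept.
    """
    df = pd.DataFrame(
        _DESIGN_ROWS,
        columns=["run", "ethanol_pct", "temp_C", "time_min", "hep2c", "rd", "l2ob"],
    )
    if response is None:
        return df
    if response not in CELL_LINES:
        raise KeyError(f"unknown response {response!r}; choose from {CELL_LINES}")
    out = df[["run", "ethanol_pct", "temp_C", "time_min", response]].copy()
    out.insert(4, "replicate", 1)
    return out.rename(columns={response: "response"})


def run_means(response: str) -> np.ndarray:
    """Mean responses of the 8 runs in standard order."""
    return factorial_design()[response].to_numpy(dtype=float)


def rate_constants(response: str | None = None) -> pd.DataFrame:
    """Diffusion-model slow-rate constants (per minute) vs temperature.

    Matches the `rates` schema; series_id is "<cell line>_<ethanol>pct".
    """
    rows = []
    for line, etoh, ks in _RATE_ROWS:
        if response is not None and line != response:
            continue
        for temp, k in zip((30.0, 40.0, 50.0), ks):
            rows.append((f"{line}_{etoh}pct", temp, k))
    return pd.DataFrame(rows, columns=["series_id", "temp_C", "k"])


def activity_panel() -> pd.DataFrame:
    """Nine-condition x eight-assay IC50 matrix (ug/mL)."""
    df = pd.DataFrame(_PANEL_ROWS, columns=("condition_id",) + _PANEL_COLUMNS)
    return df.set_index("condition_id")
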