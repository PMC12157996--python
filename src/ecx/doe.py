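"""Two-level full factorial design: fitting, ANOVA, contribution, reduction.

The model is the saturated first-order polynomial on coded factors,

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + ... ,

with every x in {-1, +1}. On a complete 2^k design the columns are
orthogonal, so each coefficient is a contrast mean of the run means and
coincides exactly with the least-squares solution; dropping insignificant
terms never changes the remaining coefficients.

Two sum-of-squares conventions are supported. "paper_runs" takes
SS(term) = n_runs * b^2 (the convention under which published effect tables
of this kind are internally consistent with their printed coefficients);
"total_observations" takes SS(term) = N_obs * b^2, the textbook effect sum
of squares when replicates enter the decomposition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DesignError, FitError, RunConfig


def term_names(k: int) -> list[str]:
    """Saturated model terms for k factors: b0, b1, ..., b12, ..., b12..k."""
    names = ["b0"]
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(1, k + 1), size):
            names.append("b" + "".join(str(i) for i in combo))
    return names


def term_label(name: str) -> str:
    """Human-readable factor label: 'b13' -> 'x1x3', 'b0' -> 'intercept'."""
    if name == "b0":
        return "intercept"
    return "".join(f"x{c}" for c in name[1:])


def _term_columns(coded: np.ndarray) -> pd.DataFrame:
    """Model matrix (runs x 2^k terms) from coded levels (runs x k)."""
    n, k = coded.shape
    cols: dict[str, np.ndarray] = {"b0": np.ones(n)}
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            name = "b" + "".join(str(i + 1) for i in combo)
            cols[name] = np.prod(coded[:, list(combo)], axis=1)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class FactorDef:
    """Actual low/high levels of one factor, for coding real-unit columns."""

    name: str
    low: float
    high: float

    def code(self, actual: np.ndarray) -> np.ndarray:
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return (np.asarray(actual, dtype=float) - mid) / half


class FactorialModel:
    """Complete 2^k factorial design with replicate responses.

    Parameters
    ----------
    coded : array-like, shape (n_runs, k)
        Coded factor levels, each entry in {-1, +1}; every combination must
        appear exactly once.
    responses : array-like, shape (n_runs, n_reps)
        Replicate responses per run (n_reps >= 1, equal across runs).
    factor_names : sequence of str, optional
        Defaults to x1..xk.
    """

    def __init__(self, coded, responses, factor_names=None):
        coded = np.asarray(coded, dtype=float)
        if coded.ndim != 2:
            raise DesignError("coded levels must be a 2-D array (runs x factors)")
        n_runs, k = coded.shape
        if not np.all(np.isin(coded, (-1.0, 1.0))):
            raise DesignError("coded levels must all be -1 or +1")
        expected = {tuple(p) for p in itertools.product((-1.0, 1.0), repeat=k)}
        seen = [tuple(row) for row in coded]
        missing = expected - set(seen)
        if len(seen) != len(set(seen)) or missing:
            raise DesignError(
                "not a complete 2^k design; missing combinations: "
                + ", ".join(map(str, sorted(missing)))
            )
        resp = np.asarray(responses, dtype=float)
        if resp.ndim == 1:
            resp = resp[:, None]
        if resp.shape[0] != n_runs:
            raise DesignError("responses must have one row per run")
        if not np.all(np.isfinite(resp)):
            raise DesignError("responses must be finite")
        self.coded = coded
        self.responses = resp
        self.k = k
        self.n_runs = n_runs
        self.n_reps = resp.shape[1]
        self.factor_names = list(factor_names or (f"x{i+1}" for i in range(k)))

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors: list[FactorDef], response: str = "response"):
        """Build from a long-format table with actual factor levels.

        `df` needs one column per factor (named as in `factors`), a
        `replicate` column and the response column. Levels are coded from
        each factor's low/high.
        """
        coded_cols = [f.code(df[f.name].to_numpy()) for f in factors]
        coded = np.column_stack(coded_cols)
        reps = sorted(df["replicate"].unique())
        combos = sorted({tuple(r) for r in coded})
        rows, resp = [], []
        for combo in combos:
            mask = np.all(np.isclose(coded, combo), axis=1)
            sub = df.loc[mask]
            vals = [float(sub.loc[sub["replicate"] == r, response].iloc[0]) for r in reps]
            rows.append(combo)
            resp.append(vals)
        return cls(np.array(rows), np.array(resp), [f.name for f in factors])

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        config: RunConfig | None = None,
        error_ss: float | None = None,
        error_df: int | None = None,
    ) -> "FactorialResults":
        """Estimate coefficients, ANOVA table, contributions and diagnostics.

        With a single replicate there is no pure-error degree of freedom;
        an external `error_ss`/`error_df` pair (e.g. from a published
        replicate analysis) must then be supplied.
        """
        config = config or RunConfig()
        run_means = self.responses.mean(axis=1)
        X = _term_columns(self.coded)
        # contrast means == OLS on the orthogonal design
        params = pd.Series(
            {name: float(np.mean(X[name].to_numpy() * run_means)) for name in X.columns},
            name="coefficient",
        )
        n_obs = self.n_runs * self.n_reps
        if error_ss is None:
            if self.n_reps < 2:
                raise FitError(
                    "no pure-error degrees of freedom with a single replicate; "
                    "supply an external error_ss and error_df"
                )
            error_ss = float(np.sum((self.responses - run_means[:, None]) ** 2))
            error_df = n_obs - self.n_runs
        elif error_df is None:
            raise FitError("error_df must accompany error_ss")
        else:
            # external pure-error estimate: its df implies the true
            # observation count (df_error = N_obs - n_runs)
            n_obs = self.n_runs + int(error_df)
        return FactorialResults(
            params=params,
            error_ss=float(error_ss),
            error_df=int(error_df),
            n_runs=self.n_runs,
            n_obs=n_obs,
            config=config,
            model=self,
        )


class FactorialResults:
    """Fitted 2^k factorial model: coefficients, ANOVA, diagnostics.

    Usually produced by :meth:`FactorialModel.fit`; can also be constructed
    directly from known coefficients plus an external error estimate via
    :meth:`from_params` (useful when only run means and a published error
    sum of squares are available).
    """

    def __init__(self, params, error_ss, error_df, n_runs, n_obs, config, model=None):
        self.params = params
        self.error_ss = error_ss
        self.error_df = error_df
        self.n_runs = n_runs
        self.n_obs = n_obs
        self.config = config
        self.model = model
        self.anova = self._anova()
        self.pc_percent = percentage_contribution(self.params)
        self.retained_terms = self._retain(config.alpha)
        self.rsquared, self.rsquared_adj, self.cv_percent = self._diagnostics()

    @classmethod
    def from_params(
        cls,
        params: dict[str, float] | pd.Series,
        error_ss: float,
        error_df: int,
        config: RunConfig | None = None,
    ) -> "FactorialResults":
        params = pd.Series(params, name="coefficient", dtype=float)
        k = int(np.log2(len(params)))
        if 2**k != len(params):
            raise DesignError("coefficient map must have 2^k entries (saturated model)")
        n_runs = 2**k
        return cls(
            params=params,
            error_ss=float(error_ss),
            error_df=int(error_df),
            n_runs=n_runs,
            n_obs=n_runs + int(error_df),
            config=config or RunConfig(),
        )

    # -- ANOVA ------------------------------------------------------------

    def _anova(self) -> pd.DataFrame:
        terms = [t for t in self.params.index if t != "b0"]
        n = self.n_runs if self.config.ss_convention == "paper_runs" else self.n_obs
        ss = {t: n * float(self.params[t]) ** 2 for t in terms}
        ms_error = self.error_ss / self.error_df if self.error_df > 0 else np.nan
        rows = []
        for t in terms:
            if ms_error == 0:
                warnings.warn("zero error mean square; F reported as infinite")
                f = np.inf
                p = 0.0
            else:
                f = ss[t] / ms_error
                p = float(stats.f.sf(f, 1, self.error_df))
            rows.append((term_label(t), ss[t], 1, ss[t], f, p))
        rows.append(("Error", self.error_ss, self.error_df, ms_error, np.nan, np.nan))
        total_ss = sum(ss.values()) + self.error_ss
        rows.append(("Total", total_ss, self.n_obs - 1, np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"]).set_index("source")

    def _retain(self, alpha: float) -> list[str]:
        kept = ["b0"]
        for t in self.params.index:
            if t == "b0":
                continue
            p = self.anova.loc[term_label(t), "p"]
            if p < alpha:
                kept.append(t)
        return kept

    def reduce(self, alpha: float | None = None) -> "FactorialResults":
        """Re-apply term retention at a (possibly different) alpha.

        The design is orthogonal, so coefficients are untouched; only the
        retained set changes.
        """
        alpha = self.config.alpha if alpha is None else alpha
        self.retained_terms = self._retain(alpha)
        return self

    def _diagnostics(self):
        ss_total = float(self.anova.loc["Total", "SS"])
        if ss_total == 0:
            return 1.0, 1.0, 0.0
        r2 = 1.0 - self.error_ss / ss_total
        df_total = self.n_obs - 1
        r2_adj = 1.0 - (self.error_ss / self.error_df) / (ss_total / df_total)
        grand_mean = float(self.params["b0"])
        if grand_mean == 0:
            raise FitError("grand mean is zero; CV undefined")
        ms_error = self.error_ss / self.error_df
        cv = 100.0 * np.sqrt(ms_error) / grand_mean
        return r2, r2_adj, cv

    # -- prediction -------------------------------------------------------

    def predict(self, coded_points, reduced: bool = True) -> np.ndarray:
        """Evaluate the (reduced) polynomial at coded points in [-1, 1]^k.

        Points outside the cube are extrapolations; a warning is emitted
        and the value still returned.
        """
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        if np.any(np.abs(pts) > 1):
            warnings.warn("coded point outside [-1, 1]^k: extrapolating")
        X = _term_columns_free(pts, int(np.log2(len(self.params))))
        terms = self.retained_terms if reduced else list(self.params.index)
        y = np.zeros(pts.shape[0])
        for t in terms:
            y += self.params[t] * X[t].to_numpy()
        return y if y.size > 1 else float(y[0])

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        lines = ["2^k factorial fit", "=" * 50]
        lines.append(f"runs: {self.n_runs}  observations: {self.n_obs}")
        lines.append(f"config: {self.config.echo()}")
        lines.append("")
        lines.append(f"{'term':<10}{'coef':>12}{'PC %':>10}{'retained':>10}")
        for t in self.params.index:
            pc = self.pc_percent.get(t, np.nan)
            pc_s = f"{pc:10.2f}" if np.isfinite(pc) else " " * 10
            mark = "yes" if t in self.retained_terms else "no"
            lines.append(f"{term_label(t):<10}{self.params[t]:12.4f}{pc_s}{mark:>10}")
        lines.append("")
        lines.append(self.anova.to_string(float_format=lambda v: f"{v:.6g}"))
        lines.append("")
        lines.append(
            f"R2 = {self.rsquared:.4f}  R2_adj = {self.rsquared_adj:.4f}  "
            f"CV% = {self.cv_percent:.2f}"
        )
        return "\n".join(lines)

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Result bundle for :func:`ecx.io.write_report`."""
        coef = pd.DataFrame(
            {
                "term": [term_label(t) for t in self.params.index],
                "coefficient": self.params.to_numpy(),
                "PC_percent": [self.pc_percent.get(t, np.nan) for t in self.params.index],
                "retained": [t in self.retained_terms for t in self.params.index],
            }
        )
        return {"coefficients": coef, "anova": self.anova.reset_index()}


def _term_columns_free(points: np.ndarray, k: int) -> pd.DataFrame:
    """Model-matrix columns at arbitrary (not just corner) coded points."""
    n = points.shape[0]
    cols: dict[str, np.ndarray] = {"b0": np.ones(n)}
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            name = "b" + "".join(str(i + 1) for i in combo)
            cols[name] = np.prod(points[:, list(combo)], axis=1)
    return pd.DataFrame(cols)


def percentage_contribution(params: pd.Series | dict[str, float]) -> pd.Series:
    """Share of total absolute effect magnitude per non-intercept term.

    PC(term) = 100 |b_term| / sum |b_other terms|. If every effect is zero
    the split is undefined; a uniform split is returned with a warning.
    The contributions sum to exactly 100.
    """
    params = pd.Series(params, dtype=float)
    terms = [t for t in params.index if t != "b0"]
    mags = params[terms].abs()
    total = float(mags.sum())
    if total == 0:
        warnings.warn("all effects are zero; percentage contribution undefined, returning uniform")
        return pd.Series(100.0 / len(terms), index=terms, name="PC_percent")
    pc = 100.0 * mags / total
    return pc.rename("PC_percent")
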