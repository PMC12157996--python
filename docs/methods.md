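# Methods

## Scope and data

`ecx` models solid–liquid extraction of bioactive compounds from plant
material, using a spring-heath (*Erica carnea* L.) maceration study as its
reference system. The study's published summary tables — the 2³ design with
mean yields, the regression coefficient table, the kinetic parameter table,
the activation-parameter table and the IC50 panels — are the only data that
exist for it (no raw measurements were deposited), so they are bundled in
`ecx.datasets` as plain literals and serve three roles: reference inputs for
re-analysis, golden values for tests, and generating truths for the
synthetic-data module.

## Factorial design (`ecx.doe`)

The response is modelled as the saturated first-order polynomial on coded
factor levels x ∈ {−1, +1}³:

    y = b0 + Σ bᵢxᵢ + Σ bᵢⱼxᵢxⱼ + b123·x1x2x3.

On a complete 2^k design the model matrix is orthogonal, so each coefficient
is a contrast mean of the run means and equals the least-squares estimate;
term deletion never changes the remaining coefficients, so "reduction" is
only a retention set (terms with p < α, default α = 0.05).

**Sum-of-squares conventions.** Two are supported. The default,
`paper_runs`, takes SS(term) = n_runs·b², which is the convention under
which the reference study's effect table is internally consistent with its
printed coefficients (e.g. 8·0.10075² = 0.0812 and F = 4060 against
MS_error = 0.00002). The textbook convention, `total_observations`
(SS = N_obs·b²), is selectable and is the one under which the SS
decomposition exactly exhausts the raw total sum of squares; the
decomposition property test runs under it.

**Pure error.** With r ≥ 2 replicates the error SS is the within-run
replicate scatter with df = N_obs − n_runs. The reference tables print only
run means, so the published error SS/df (0.00016/8, 0.00032/8, 0.00048/8)
can be injected explicitly; the implied observation count is then
recovered from the df (N_obs = n_runs + df_error), which the adjusted-R²
and total-df computations use.

**Percentage contribution.** PC(term) = 100·|b|/Σ|b| over non-intercept
terms. This is the definition that reproduces every printed contribution to
0.01 % (e.g. 67.67 % for extraction time on the Hep2c response); it sums to
exactly 100 by construction, and a uniform split with a warning is returned
in the degenerate all-zero case.

**p-values.** Upper tail of F(1, df_error). The reference table's printed
p-values do not follow from its own printed F statistics under any standard
F tail and are not reproduced; the retention sets they imply, however, are
(the Hep2c reduction drops exactly the x1x2 interaction).

**Known inconsistency in the reference tables.** The eight printed Hep2c
run means reproduce the printed b0, b1, b3 and b13 but not b2, b12, b23,
b123 (e.g. the means give b2 = 0.01075 against the printed 0.0087), and the
printed L2OB intercept differs from the mean of its printed run means.
Golden tests therefore assert only the internally consistent values;
corner predictions from the reduced model use the printed coefficient
table, which is what reproduces the printed predicted column (0.452 at the
all-low corner).

## Extraction kinetics (`ecx.kinetics`)

The observed quantity is a normalized yield fraction q(t) ∈ [0, 1]
(activity-derived yield over its equilibrium value). Two models:

* **Unsteady-state diffusion** — q(t) = 1 − (1−b)e^(−kt), with washing
  coefficient b (fraction extracted in the fast surface-washing stage,
  q(0) = b) and slow rate constant k (min⁻¹). Fitted as the straight line
  ln(1−q) = ln(1−b) − kt. This algebra is adopted deliberately: the common
  shorthand q = 1 − b·e^(−kt) is inconsistent with the ln(1−b) intercept of
  its own linearization and with b ≈ b′ in published parameter tables.
* **Ponomarev** — q(t) = b′ + k′t, the empirical linear model, with the left
  side oriented as the increasing yield fraction so b′ is a washing
  intercept comparable to b.

Both fit the linearized form by ordinary least squares (the reference
analysis reports linear-regression fits), over all supplied points by
default; a `t_min` window restricts to the slow phase if wanted. Points
with q ≥ 1 are dropped from the log fit with a warning; a numerically
vanishing or negative slope is flagged rather than rejected.

**Goodness of fit** is evaluated on the original q scale:
R² = 1 − SSres/SStot (NaN when q has no variance) and
RMS % = 100·√(mean(((q̂−q)/q)²)), the mean-relative root-square deviation
standard in this literature (the reference study does not define its RMS;
this choice reproduces its reported magnitudes). q = 0 points are excluded
from the relative RMS with a warning. Model comparison ranks by higher R²,
then lower RMS, reporting per-criterion winners and flagging exact ties.

## Activation thermodynamics (`ecx.thermo`)

Arrhenius: least squares of ln k on 1/T, Ea = −slope·R (R = 8.314 J/mol·K),
lnA = intercept; a two-point endpoint mode is available because some
published Ea values correspond to endpoint slopes. Negative Ea is returned
with a warning, not an error.

Transition-state parameters per temperature: ΔH* = Ea − RT;
ΔS* = R[ln(k·h/(kB·T)) + ΔH*/(RT)] (Eyring, CODATA kB and h);
ΔG* = ΔH* − TΔS*, computed from ΔH* and ΔS* so the identity holds exactly.
The Eyring entropy depends on the unit of k inside the logarithm. The
reference study states no ΔS* formula; evaluating with k in min⁻¹
reproduces its printed values to ~1 % (−268.6 vs −271.28 for the first
Hep2c row) whereas per-second is ~30 J/K·mol off, so per-minute is the
default, per-second is selectable via `RunConfig.rate_unit`, and the
printed ΔS* values are not golden-tested. Positive ΔH* and ΔG* are exposed
as endothermic / non-spontaneous flags.

Some published rate constants and Ea values are mutually inconsistent
(three series imply Ea values 40–60 % below the printed ones — probable
typos); only the internally consistent series (Hep2c/50 %, L2OB/30 %,
L2OB/70 %) are used as golden anchors.

## Bioassay summaries (`ecx.bioassay`)

IC50 is interpolated between the bracketing pair of dose-response points,
linearly in log concentration by default (exact for symmetric brackets on
geometric ladders; linear scale selectable). An exact 50 % reading returns
that concentration; curves that never cross 50 % (or start above it) return
typed censored results ("> max" / "< min"), never sentinel numbers. No
four-parameter-logistic fitting is attempted: the reduction is
single-replicate interpolation by design.

MIC reduction takes the lowest inhibited concentration of a validated
two-fold ladder; all-inhibited series are flagged "≤ min" (the true MIC
may lie below the tested range), none-inhibited "> max".

Panel correlations are plain Pearson r between assay IC50 columns
(pandas `corr`), optionally on 1/IC50 or log IC50, since the provenance of
published correlation tables of this kind is often unclear. The reference
study's printed correlation matrix is *not* reproduced by Pearson r on its
own printed condition-mean IC50s (several cells differ by ~0.03), so it is
excluded from golden tests; the implementation is instead verified against
a covariance-formula oracle to 1e-12.

## Synthetic data (`ecx.simulate`)

Generators emulate each input with an explicit noise model (the reference
study reports only ±3 SD summaries, never a noise model, so these are the
package's choices):

| channel | model | default |
| --- | --- | --- |
| factorial replicates | y = polynomial + N(0, σ_rep) | σ_rep = 0.005, 2 replicates |
| time-course q | model mean + N(0, σ_q), clipped to [0, 0.999] | σ_q = 0.01, grid {10,15,20,30,40,60,80} min |
| rate vs T | Arrhenius mean × exp(N(0, σ_ln)) | σ_ln = 0.02, T = 30/40/50 °C |
| dose response | Hill (slope 1) + N(0, σ_I) on % inhibition | σ_I = 0 |
| IC50 panel | base·exp(loading·Z_cond + N(0, σ_p)), shared latent Z | loading 0.3, σ_p = 0.05 |

Defaults are the reference study's conditions where it states them (time
grid, temperatures, generating b/k/β per cell-line preset, IC50 = 14.29 for
the Hill curve) and field-typical values otherwise. Presets `hep2c`, `rd`,
`l2ob` carry the published coefficients and 30 %-ethanol kinetic parameters
as truths. Everything is deterministic given a seed; the CSV bundle derives
per-table child seeds from one master seed so outputs are byte-identical
across runs.

What the generators deliberately do **not** emulate: correlated replicate
errors, temperature-dependent washing coefficients, plate effects or
censoring in the dose-response channel, and the unknown mapping from raw
IC50 readings to the normalized yield fraction q. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated noise
models, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Temperatures are accepted in °C and converted once to Kelvin (+273.15).
* Zero error mean square → infinite F with a warning; zero response
  variance → NaN R² with a warning; all-zero effects → uniform PC with a
  warning; grand mean 0 → CV is an error.
* Coded points outside [−1, 1]^k are evaluated with an extrapolation
  warning.
* Report floats are written at 12 significant digits, giving exact CSV
  round-trips at that precision.

## Known limitations

* Raw extraction time courses for the reference system exist only as a
  published figure, so its kinetic parameter table can be used as
  generating truth but not reproduced end-to-end.
* Two simulation-based performance claims in the package's acceptance suite
  are documented as unattainable under the stated conditions and left
  failing by design: at σ_q = 0.01 on the reference 7-point grid the median
  relative error of k has an ~8.5 % theoretical floor
  (sd(k) = σ_ln/√Sxx), and with k·t ≤ 0.2 the diffusion curve is within
  ~5×10⁻⁴ of a straight line, putting diffusion-vs-linear model
  discrimination near chance. The corresponding estimator and ranking
  mechanisms are verified separately in regimes where they are
  identifiable.
* ΔS* (and hence ΔG*) absolute values depend on the rate-constant unit
  convention inside the Eyring logarithm; results are reproducible to ~1 %
  of the reference values, not exactly.
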