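# Methods

## Model

The forecaster treats a uniformly sampled HR series as
`f_t = g_t + r_t`: a smooth deterministic part `g` (exercise-driven trend
plus quasi-periodic structure) and a serially dependent stochastic residual
`r`.  The two parts are modelled, predicted and recombined separately.

### Deterministic part: singular spectrum analysis

The training window of length `train_length` is embedded into the L×K
Hankel trajectory matrix (window `ssa_window = L`, K = N − L + 1; we accept
L = K, where the middle branch of the diagonal-averaging formula is simply
empty, rather than failing on the boundary).  The SVD's leading
`ssa_components = I` triples form the trend group; anti-diagonal averaging
maps the grouped matrix (which is generally no longer Hankel) back to a
series.  Singular values below 1e−12 of the largest are treated as zero
when determining the effective rank d; if a noise-free signal has rank
below the requested I, the fit silently uses d components (the summary
reports both).  Ties among singular values keep the SVD's returned order,
so grouping by index is basis-dependent in the tied case.

Extrapolation uses recurrent SSA forecasting: with `π` the last-row
components of the leading left singular vectors and `ν² = |π|²` the
verticality, the recurrence coefficients are `R = (1 − ν²)⁻¹ Σ π_i U_i∇`,
applied iteratively to the reconstructed trend's last L − 1 values.  This is
the canonical linear-recurrence forecasting method and needs no extra
parameters; `ν²` within 1e−10 of 1 raises a diagnostic error instead of
returning garbage.  Forecasting 0 steps returns an empty sequence.

### Stochastic part: pair copulas on a lagged residual matrix

Residuals are arranged in a matrix with `residual_window = W` columns at
`residual_delay = 1`, so adjacent columns are lag-1 pairs of the residual
process.  Each column gets an empirical marginal: sorted values at plotting
positions `i/(n+1)` with linear interpolation, and a linearly interpolated
quantile function clamped to the observed min/max (no extrapolation outside
the sample).  Ranks use averaging for ties, keeping pseudo-observations
strictly inside (0, 1).

For each adjacent column pair (or one pooled pair when
`share_pair_copula=True` — the columns are lag-translates of one process,
so pooling is statistically coherent and much cheaper) a copula family is
fitted:

* **Maximum likelihood** on pseudo-observations (canonical ML; marginals
  are explicitly empirical, so parametric-margin ML does not apply).  The
  1-D search runs Nelder–Mead over an unconstrained reparameterisation of
  each family's domain (Clayton θ = −1 + eˢ, Frank θ = s, Gumbel
  θ = 1 + eˢ), multi-started from a Kendall-tau moment guess and a domain
  midpoint.  |θ| < 1e−8 (Clayton/Frank) and θ − 1 < 1e−8 (Gumbel) are the
  independence copula — a removable singularity, evaluated exactly.
* **Family selection** (`copula_family="auto"`) fits Clayton, Frank and
  Gumbel and picks the minimum Cramér–von Mises distance
  `Σ_i (C_e(u_i,v_i) − C_θ(u_i,v_i))²` between the fitted CDF and the
  empirical copula at the pseudo-observations.  No bootstrap p-values: the
  statistic is used only to rank families.  The empirical-copula evaluation
  is capped at 2,000 evenly spaced sample points (ML always uses the full
  sample), bounding the O(points × n) cost.
* Degenerate residual columns (range < 1e−12) and failed fits fall back to
  the independence copula, logged per pair.

The Frank CDF is implemented in its standard form
`−(1/θ) ln(1 + (e^{−θu}−1)(e^{−θv}−1)/(e^{−θ}−1))`; the Gumbel exponent is
read as `(−ln u)^θ`, consistent with its generator.  Both boundary
identities `C(u,1) = u`, `C(1,v) = v` and the grounded boundary are patched
exactly at the edges of the unit square.

**Conditional prediction.**  At step h the latest residual (observed at
h = 1, predicted thereafter) is mapped to rank space through the current
column's marginal CDF, `n_conditional_samples` draws are taken from the
pair copula's conditional distribution by inverse transform on the
h-function ∂C/∂u (closed-form inverse for Clayton θ > 0 and Frank;
vectorised bisection, tolerance 1e−10, ≤ 200 iterations, for Gumbel and
negative-θ Clayton), each draw is mapped back through the *next* column's
inverse marginal (the next column is the variable being predicted), and
the sample mean becomes both the step-h residual prediction and the next
conditioning value.  Step h uses pair index min(h, W − 1): a horizon equal
to W would need a (W, W+1) pair that does not exist, and the last pair is a
lag-translate of it.  All sampling flows from one seeded generator derived
from the configuration seed, so predictions are bit-reproducible.

The hybrid forecast is deterministic + stochastic, element-wise, always;
optional clamping to the physiological amplitude range (default 25–240 bpm)
is off by default so the additivity is visible to tests.

### Sliding evaluation

`evaluate` slides the prediction origin by `slide_step`, refits on the
preceding `train_length` epochs (full refit per origin by default), records
|forecast − observed| per step, and returns per-step means (MAE, bpm) with
the origin count; the deterministic-only errors can be recorded alongside
for paired comparisons at zero extra cost.  `refit_every = k` reuses the
stored recurrence and copulas at intermediate origins, seeding the
recurrence from the raw series tail and approximating the conditioning
residual with a one-step recurrence estimate — a documented fidelity/speed
trade for long evaluations, not used by the default settings.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `train_length` | 1500 | epochs (s) | reference training-window length |
| `slide_step` | 1 | epochs | reference sliding step |
| `ssa_window` L | 750 | epochs | half the training window, the standard choice when no window is prescribed |
| `ssa_components` I | 60 | — | reference trend-group size |
| `residual_window` W | 30 | epochs | lagged residual matrix width |
| `residual_delay` | 1 | epochs | lag between adjacent columns |
| `horizon` H | 30 | epochs (s) | short-term forecast length; H ≤ W |
| `n_conditional_samples` | 3000 | — | conditional draws averaged per step |
| `copula_family` | auto | — | per-pair GoF selection |
| `seed` | 0 | — | all randomness |

## Synthetic data

`generate_hr` emulates a four-phase outdoor running session (flat → uphill
→ downhill → flat; boundaries 465/1112/1547 s, total 2634 s at 1 Hz).  HR
responds to each phase's target plateau through a first-order exponential
lag with time constant τ = 30 s (the onset delay of cardiovascular
response; configurable), plus a mild periodic component (3 bpm, 300 s) and
one of three noise models — white, AR(1) (σ is the stationary sd, in
bpm), or a copula-chained
noise whose consecutive values follow a chosen Archimedean family (this
path doubles as an integration test of the conditional sampler); the
reference study condition is AR(1) with φ = 0.8, σ = 2 bpm.  Values
are clipped to 25–240 bpm.  Plateau levels (90/165/150/155 bpm) are
documented generator constants, not claims about any real subject.

What the generator does *not* emulate: measurement artefacts and dropouts,
breathing-rate coupling, inter-subject variability, slope/GPS physics, and
non-stationary residual dependence.  Tests passing on this generator show
the pipeline is correct and that the copula stage exploits serial
dependence when it exists; they do not certify accuracy on real wearable
data, whose MAE depends on the subject and session.

## Numerical choices

* Copula arguments are clipped to [1e−12, 1 − 1e−12] before interior
  formulas; boundary identities are patched exactly.
* Diagonal averaging uses bincount sums over anti-diagonal indices; the
  Hankel round-trip is exact to IEEE round-off (averaging k identical
  doubles can round in the last ulp, so "exact" means ≲ 1e−12 relative).
* Rank-transform conditioning values are clipped to [1e−9, 1 − 1e−9]
  before h-function inversion.
* Marginal quantile functions clamp outside the observed range rather than
  extrapolate.
* Per-origin RNG streams are spawned as `SeedSequence([seed, origin])`, so
  evaluations are reproducible regardless of how many origins are run.

## Study sizes used by the test suite

The default configuration mirrors the reference protocol (1,500 training
epochs, L = 750, I = 60).  The end-to-end studies in the test suite run at
desk scale — train 512, L = 128, I = 8, with evaluation origins spread
across all four protocol phases by larger slide steps (40–100), and a
pooled Frank pair copula for the 20-seed paired step-1 comparison (the
AR(1) Gaussian residual has symmetric dependence) — sizes chosen so a full
suite run stays in minutes while every stage of the pipeline is exercised
end to end.

## Known limitations

* The SSA recurrence can extrapolate poorly through abrupt phase
  transitions (origins in the steep uphill onset show the largest long-
  horizon errors); the copula stage corrects only the serially dependent
  residual, not trend-extrapolation bias.
* Family selection is argmin over three candidates; no significance
  statement is attached to the chosen family.
* The conditional-mean chain propagates point predictions, not predictive
  distributions; multi-step uncertainty is understated if residual
  dependence is strong beyond lag 1.
* Only bivariate (adjacent-column) dependence is modelled; higher-order
  residual structure is ignored by design.
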