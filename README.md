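# ssacopula

Short-term heart-rate (HR) forecasting for wearable 1 Hz HR streams, built
for exercise-physiology and health-monitoring workflows where the next
half-minute of HR matters (load control, early warning during training).

The forecaster is a hybrid of a deterministic and a stochastic model:

1. **Singular spectrum analysis (SSA)** extracts the smooth deterministic
   part.  The series *f₁…f_N* is lag-embedded into the L×K Hankel trajectory
   matrix **X** (K = N − L + 1), decomposed by SVD into elementary matrices
   *X_i = √λ_i U_i V_iᵀ*, the leading *I* components are Hankelized back into
   a trend by anti-diagonal averaging, and the trend is extrapolated with the
   linear recurrence implied by *U₁…U_I* (recurrent SSA forecasting).
2. **Archimedean pair copulas** model the residual ("anomaly")
   *r = f − trend*.  Residuals are arranged in a lagged matrix (window W = 30,
   delay 1); adjacent columns are rank-transformed to pseudo-observations
   *uᵢ = rank/(n+1)*, and a Clayton, Frank or Gumbel copula
   *C(u,v) = φ⁻¹(φ(u) + φ(v))* is fitted per column pair by maximum
   likelihood, with the family selected by a Cramér–von Mises distance to the
   empirical copula *C_e(u,v) = n⁻¹ Σ 𝟙(uᵢ ≤ u, vᵢ ≤ v)*.  Residual
   prediction chains one-step conditional means: sample the h-function
   *∂C/∂u* inverse, back-transform through the next column's empirical
   quantile function, average.

The forecast at each step is the sum of the two parts; accuracy is reported
as mean absolute error (MAE, bpm) per forecast step over sliding origins.

## Worked example

```python
import ssacopula as sc

series = sc.generate_hr(sc.default_running_profile(), seed=3)  # synthetic 1 Hz run
cfg = sc.PredictorConfig(
    train_length=512, ssa_window=128, ssa_components=8,
    residual_window=30, horizon=30, n_conditional_samples=1000,
    seed=3, copula_family="auto",
)
results = sc.HybridHRForecaster(series.values[:512], cfg).fit()
print(results.summary())
pred, det, sto = results.predict(return_components=True)
table = sc.evaluate(series, cfg, slide_step=40)
```

`summary()` reports the fitted state — 29 pair copulas (all Frank for this
AR(1)-noise session), residual sd 1.30 bpm, SSA verticality ν² = 0.194:

```
Hybrid SSA + copula heart-rate model
============================================
training epochs        512
SSA window / components 128 / 8
effective rank d       128
leading singular value 2.029e+04
verticality nu^2       0.1941
residual sd (bpm)      1.298
residual window/delay  30 / 1
pair copulas           29
families               {'frank': 29}
conditional draws/step 1000
seed                   3
config hash            1581e4d7c5af
```

The forecast decomposes additively per step (bpm); the stochastic part pulls
the first steps toward the last observed residual:

```
step  forecast  deterministic  stochastic  actual
   1    147.63         147.87       -0.24  148.16
   2    147.73         147.91       -0.18  150.71
   3    147.74         147.89       -0.15  150.04
```

Sliding evaluation over 53 origins spread across the whole session shows the
copula residual model earning its keep at short horizons:

```
MAE step  1: hybrid 1.30 bpm, SSA-only 1.89 bpm
MAE step  7: hybrid 2.57 bpm, SSA-only 2.61 bpm
MAE step 30: hybrid 5.68 bpm, SSA-only 5.68 bpm
```

The same pipeline runs from the shell:

```bash
ssacopula simulate --out hr.csv --seed 3
ssacopula run --input hr.csv --out-dir out --train-length 512 \
    --ssa-window 128 --ssa-components 8 --seed 3
```

writing trend/residual/forecast/MAE CSVs, plots, and a manifest naming the
seed and configuration hash.

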