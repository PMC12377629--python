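# frontiercar

Bayesian boundary detection ("wombling") for areal health data: Poisson
log-linear disease mapping with a **dissimilarity-adjusted localized
conditional autoregressive (CAR) prior**, so that spatial smoothing of
relative risks can break across sharp socioeconomic discontinuities —
*social frontiers* — between adjacent areal units.

The package is aimed at spatial epidemiologists and social scientists who
work with small-area count data (e.g. census-tract child mortality) and
want to ask not only *where risk is high* but *where risk changes
abruptly across a border*, and whether those step changes line up with
structural inequality between neighboring areas.

## Model

For areal units `k = 1, …, K` with observed counts `Y_k` and expected
counts `E_k` from internal indirect standardization
(`E_k = n_k · ΣY/Σn`, so `ΣE = ΣY`):

```
Y_k | E_k, R_k ~ Poisson(E_k R_k)
ln(R_k) = x_kᵀ β + φ_k
```

The random effects `φ` get a CAR prior whose neighbor weights are
attenuated by an edge dissimilarity metric — here the absolute difference
of hardship-index deciles `z_ij ∈ {0, …, 9}` between adjacent units:

```
w*_ij(α) = w_ij · exp(−α z_ij)
φ ~ N(0, τ² Q(α)⁻¹),   Q(α) = diag(W* 1) − W* + ε I
```

`w_ij` is the binary queen/rook contiguity indicator and `ε` a small
ridge that makes the otherwise intrinsic prior proper. The dissimilarity
coefficient `α` is estimated jointly with `(β, φ, τ²)` by
Metropolis-within-Gibbs. An adjacent pair is flagged as a **step change**
when `w*_ij < 0.5` at the posterior median of `α` (equivalently
`z_ij > ln 2 / α̂`); the smallest `α` at which any pair can be flagged is

```
α_min = ln(2) / max(z)  =  0.077 on the decile scale (max z = 9).
```

A posterior for `α` lying above `α_min` is evidence that the
dissimilarity metric marks real discontinuities in the risk surface.

Supporting computation includes decile scoring, spatial lags, Moran's I
with a permutation test, a neighbor-difference Monte Carlo randomization
test, the Hirschman–Herfindahl index, composite-index construction,
DIC / p.d. / LMPL and Geweke diagnostics, VIF collinearity checks, and a
synthetic lattice generator with planted frontiers for validation.

## Worked example

Simulate a 12×12 tract lattice with a planted frontier down the middle
(hardship deciles 1 vs 10 meet at the divide, so every frontier edge has
`z = 9`), true covariate effect 0.3, `τ² = 0.25`, `α = 0.3`, then fit an
intercept-only model and a covariate model:

```python
from frontiercar import RunConfig, ScenarioConfig, ModelSpec, run_pipeline

cfg = RunConfig(
    scenario=ScenarioConfig(nrows=12, ncols=12, seed=1, base_rate=0.05),
    models=("model1", "model2"), covariate_names=("x1",),
    model_spec=ModelSpec(n_burn=2000, n_keep=2000, thin=1, seed=1),
)
report = run_pipeline(cfg)
print(report["model_comparison"].to_string())
```

```
                                     model1                   model2
intercept           -0.143 (-0.179, -0.109)  -0.095 (-0.129, -0.062)
tau2                   0.853 (0.589, 1.204)     0.290 (0.159, 0.442)
alpha                  0.118 (0.006, 0.731)     0.275 (0.035, 1.340)
boundary_alpha                       0.1177                   0.2749
boundary_exp_alpha                   1.1249                   1.3163
alpha_min                             0.077                    0.077
step_changes                             34                       34
DIC                                  998.18                   983.28
p_d                                  110.26                    87.62
LMPL                                -522.29                  -507.45
x1                                      NaN     0.292 (0.237, 0.352)
```

Reading the output: the covariate model recovers the true effect
(0.292 against a truth of 0.3, 95% credible interval covering it) and a
`τ²` interval covering 0.25; the posterior median of `α` sits above
`α_min = 0.077`, and the 34 flagged step changes (6.7% of the 506
borders) are exactly the 34 planted frontier edges. `boundary_exp_alpha`
is the relative-risk reading `exp(α̂)` of the boundary coefficient; DIC
and LMPL favor the covariate model, as they should when the covariate
truly drives risk.

The same pipeline runs from the shell:

```
frontiercar simulate --rows 12 --cols 12 --seed 1 --outdir sim/
frontiercar fit --table sim/study_table.csv --edges sim/edges.csv \
    --covariates x1 --burn 2000 --keep 2000 --thin 1 --seed 1 --outdir fit/
frontiercar boundaries --samples fit/samples.npz --out frontier.csv
frontiercar report --config run.yaml
```

Outputs include per-edge boundary probabilities and step-change flags
(CSV), posterior summaries with Geweke z-scores, and a GeoJSON
LineString layer joining the centroids of flagged adjacent pairs.

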