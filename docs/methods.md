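# Methods

## Model and estimation

The package fits a Poisson log-linear disease-mapping model
`Y_k ~ Poisson(E_k exp(x_kᵀβ + φ_k))` whose spatial random effects carry
a localized CAR prior: the precision of `φ` is
`τ⁻² (diag(W*1) − W* + εI)` with modified adjacency
`w*_ij(α) = w_ij exp(−α z_ij)`. The dissimilarity `z_ij` is the absolute
difference of hardship deciles between adjacent units, so `α` controls
how quickly smoothing decays with socioeconomic contrast. A pair is a
step change ("social frontier") when `w*_ij < 0.5` at the posterior
median of `α`; per-edge posterior boundary probabilities
`P(exp(−α z_ij) < 0.5 | Y)` are reported alongside the binary flags.
`α_min = ln 2 / max(z)` is the smallest `α` at which any pair can be
flagged; on the decile scale (`max z = 9`) it equals 0.077.

The sampler is Metropolis-within-Gibbs:

- **β** — blocked random-walk Metropolis against the Poisson likelihood
  and a diffuse `N(0, 10⁵)` prior, initialized at the Poisson GLM MLE
  with proposal covariance from its Fisher information.
- **φ** — single-site random-walk Metropolis against each unit's Poisson
  likelihood times its CAR full conditional
  (`mean = Σ w*φ_j/(Σw* + ε)`, `var = τ²/(Σw* + ε)`). Units are
  partitioned into independent sets by greedy graph coloring so each
  color updates as one vectorized block; this is exact because units of
  one color are mutually non-adjacent. `φ` is re-centered every sweep
  with its mean absorbed into the intercept (the ε-proper prior only
  weakly identifies the level).
- **τ²** — conjugate inverse-gamma Gibbs draw,
  `IG(a + K/2, b + φᵀQφ/2)` with prior `IG(1, 0.01)`.
- **α** — random-walk Metropolis on `log α` against the joint CAR
  density including `½ log|Q(α)|` (dense Cholesky up to K = 2000, sparse
  LU beyond), with a `Uniform(0, 50)` prior and the log-scale Jacobian.

Proposal scales adapt every 50 sweeps during burn-in only (targets 0.25
for the β block, 0.40 for scalar updates) and are frozen afterwards, so
the post-burn-in chain is a fixed Markov kernel. Every draw path is a
deterministic function of the seed.

Initialization matters more than usual here: a cold start at `φ = 0`
makes the first conjugate `τ²` draw collapse to ~`b/(a + K/2)` and
wastes much of the burn-in escaping the over-smoothed region. The chain
therefore starts `φ` at the centered residual log risk
`log((Y + ½)/E) − xᵀβ̂` and `τ²` at its variance.

Defaults: burn-in 20,000; 10,000 retained draws after thinning by 2;
`ε = 0.001`. Validation experiments use shorter chains (burn-in 2,000,
2,000 retained, thin 1), which the recovery results below show are
adequate at those problem sizes.

## Key parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `α` | dissimilarity decay of neighbor weights (per decile unit) | estimated; prior U(0, 50) | must exceed `α_min = 0.077` for any boundary to be identifiable |
| `τ²` | conditional variance of the random-effect field | estimated; prior IG(1, 0.01) | diffuse conjugate default |
| `ε` | propriety ridge on the CAR precision | 0.001 | smallest value that keeps `|Q(α)|` well-conditioned without visibly perturbing conditionals |
| `β` prior variance | 10⁵ | — | effectively flat on the log-risk scale |
| contiguity rule | queen (rook optional) | queen | the conventional default for tract lattices |
| dissimilarity units | decile (normalized optional) | decile | the decile scale is what makes the printed `α_min = 0.077 = ln2/9` threshold meaningful; the normalized variant (`z/max z`, `α_min = ln 2`) is exposed but not default |

## Synthetic data: what it emulates and what it does not

`generate_lattice_study` builds an `R×C` grid of unit squares with queen
contiguity and plants a vertical frontier: hardship follows a
within-block column ramp whose extremes meet at the divide, so with zero
noise the two border columns occupy deciles 1 and 10 and **every
frontier edge carries the maximal dissimilarity z = 9** while
within-block edges have `z ≤ 1`. (Two *flat* blocks cannot produce
`z = 9` under empirical decile scoring — massively tied groups land in
interior deciles — which is why the ramp profile is the default;
`ehi_profile="flat"` is available.) Random effects are drawn from the
localized CAR prior at the true `(α, τ²)` and centered; covariates are
i.i.d. standard normal with spatial lags; populations are
`Uniform(200, 2000)`; counts are Poisson around
`n_k · base_rate · exp(η_k)`. The default `base_rate = 0.002` reproduces
the sparse regime typical of tract-level child-mortality data (a couple
of expected events per tract). Hardship anchors (80 / 140) echo the
least/most-deprived tract means seen in large urban counties.

The generator emulates the *statistical* structure the model assumes —
lattice contiguity, clustered hardship with a sharp discontinuity,
CAR-structured residual risk, internally standardized expected counts.
It does not emulate real tract geography, irregular polygon adjacency,
ACS-style measurement error in the covariates, or spatial confounding
between covariates and the hardship surface; passing recovery tests
therefore demonstrate correctness of the estimation machinery, not
robustness to those real-data complications.

## Recovery experiments and identifiability

Parameter-recovery validation (`recovery_scenario`) uses the planted
frontier at the stated truth (`β = (−0.5, 0.3)`, `τ² = 0.25`,
`α = 0.3`) but an informative count regime (`base_rate = 0.1`, expected
counts of order 50–100 per unit). This is deliberate: at the sparse
study scale the random-effect variance and dissimilarity coefficient
are only weakly identified — profiling the CAR log density at the true
field shows an essentially flat ridge in `α`, and the `τ²` posterior
sits near its prior — so no estimator could be validated there. In the
informative regime the sampler recovers `τ²` and `α` (e.g. posterior
interval 0.17–0.28 for a truth of 0.25) and the posterior mean field
correlates > 0.93 with the true `φ`. Boundary recovery on the strong
planted frontier is exact in this regime: all cross-block edges flagged,
no within-block edges flagged. The sparse default remains what pipeline
and integration tests exercise.

The 20-replicate recovery experiment in the test suite runs 20×20
lattices at the reduced chain lengths; these sizes keep the full
validation battery to a few minutes on one CPU while leaving the
conclusions unchanged at longer chains.

## Numerical choices and degenerate inputs

- Decile ties: average ranks, then equal-frequency binning — tied units
  always share a decile; an all-constant vector is an error.
- Permutation tests use the +1-corrected pseudo p-value
  `(1 + #extreme)/(1 + n_perm)`; Moran's I tests the upper tail, the
  neighbor-difference test the lower tail (neighbors *more similar* than
  chance). Constant inputs are errors (any permutation is identical).
- Expected counts: `ΣE = ΣY` to machine precision; zero total events or
  nonpositive populations are errors naming the offending unit.
- Islands are retained with a warning; their CAR conditional shrinks to
  the prior center with variance `τ²/ε`; their spatial lag is NaN.
- CPO uses log-sum-exp throughout; a non-positive-definite `Q` raises an
  error suggesting a larger `ε`.
- Geweke z compares the first 10% with the last 50% of a chain, with
  segment variances from a Bartlett-window spectral estimate at
  frequency zero (window length `⌊√n⌋`).
- The boundary flag uses the posterior *median* of `α` (robust to the
  long right tail the U(0, 50) prior permits when `α` is weakly
  identified); probabilities over draws are reported so other rules can
  be applied downstream.
- `exp(α̂)` is reported alongside `α̂` as a relative-risk reading of the
  boundary coefficient. Note `α` parameterizes prior weights, not the
  linear predictor, so this transform is a descriptive convention, not a
  model-implied risk ratio; the package does not add a boundary
  indicator to the covariates unless the user constructs one.

## Known limitations

- Single dissimilarity metric per edge; no Leroux/BYM alternatives; no
  spatio-temporal extension.
- Polygon input is GeoJSON (or adjacency CSV); no shapefile reader and
  no CRS handling beyond pass-through.
- The composite-index builder is a generic first-principal-component
  scorer; it does not reproduce multi-factor rotations.
- Age–sex standardization against an external reference population is
  out of scope; standardization is internal and (by default) single
  stratum.
- In sparse-count regimes `τ²` and `α` inherit substantial prior
  influence; posterior medians of `α` remain usable for boundary
  flagging but their credible intervals should be read with the
  identifiability caveat above.
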