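# Methods

`supplyscape` measures the supply capacity of regional older-adult services
from a county x year x indicator panel and characterizes how that capacity
is distributed over space and time. This note records the models, the
parameters that matter, and the design choices made where the methodology
was genuinely open.

## Composite index (entropy-TOPSIS)

The raw panel is a balanced matrix of m = n_units x n_years observations on
20 indicators spanning four dimensions (social security, care service,
health support, emotional comfort). Exactly one indicator — premature
mortality of major chronic diseases — is cost-type (direction −1).

1. **Normalization.** Min-max with direction reversal:
   benefit columns map to (x−min)/(max−min), cost columns to
   (max−x)/(max−min), so every normalized column is benefit-oriented on
   [0, 1]. The normalization method is a package choice (the standard
   companion of entropy-TOPSIS; the directionality markers in the indicator
   system exist precisely for this step). Extrema are pooled over all
   unit-years by default so index levels are comparable across the decade;
   `pooling="per_year"` rescales within years. A constant column is set to
   0.5 with a warning — it carries no information and receives entropy
   weight 0.
2. **Entropy weights.** p_ij = x′_ij / Σ_i x′_ij (0/0 → 0),
   e_j = −(1/ln m) Σ_i p_ij ln p_ij with 0·ln 0 := 0, d_j = 1 − e_j,
   ω_j = d_j / Σ d_j. An all-zero column gets e_j := 1 (weight 0); all
   columns constant is an error.
3. **TOPSIS.** Weights enter once, in the weighted normalized matrix
   z_ij = ω_j x′_ij; the ideal points Z±_j are column extrema of z and the
   distances D± are unweighted Euclidean on z. (Typeset formulas sometimes
   show ω outside the distance sum; applying the weight both in z and in
   the distance would square it, contradicting the "weighted normalized
   matrix" construction, so weights are applied exactly once.) The index is
   Ci = D−/(D−+D+) ∈ [0, 1], with 1 = ideal supply.

The published per-indicator weights are packaged as a fixture
(`table1_schema`, `weight_mode="fixed"`); they are not treated as a
reproduction target because the pooling scope behind them is unknowable
without the raw yearbook data.

## Distribution dynamics (KDE)

Fixed-bandwidth Gaussian KDE, f(x) = (1/(Nh)) Σ K((X_i−x)/h), default
h = 0.05 on the Ci scale, evaluated on 512 grid points over
[min−4h, max+4h] (covering >99.99% of kernel mass; trapezoid mass of every
emitted curve is 1 ± 1%). h is a config value; no data-driven bandwidth
selection is attempted. Curve features are read off numerically: local
maxima at least 5% of the global maximum count as peaks (configurable
prominence threshold); curve width is the x-extent where f ≥ 5% of the
main peak; tail masses integrate the density beyond main peak ± width/2;
skew sign compares the two tail masses. No boundary correction is applied
at Ci ∈ {0, 1} — a known limitation shared with the standard practice this
mirrors: densities can leak mass past the unit interval.

## Mobility (classical and spatial Markov chains)

Pooled unit-year Ci values are cut at the sample quartiles (linear
interpolation between order statistics — the convention under which 610
distinct values split 153/152/152/153) into levels I–IV with boundary rule
I: c ≤ Q1, II: Q1 < c ≤ Q2, III: Q2 < c ≤ Q3, IV: c > Q3. Transition
counts pool every consecutive-year pair; probabilities are the row MLE
P_ij = n_ij/n_i, with empty rows marked undefined rather than zero-filled.

The spatial Markov chain conditions each transition on the quartile level
of the unit's spatial lag Σ_j ω_ij c_jt (row-standardized weights) in the
**origin** year t, using the same pooled cut points for lag levels as for
unit levels; the four conditional count matrices partition the
unconditional counts exactly — an identity asserted at construction.

Global Moran's I uses I = n/S0 · z′Wz / z′z with z the centered
cross-section. E(I) = −1/(n−1) exactly. The default inference is the
normality-assumption variance (closed form in S0, S1, S2); a permutation
test (default 999 seeded relabelings, one-sided toward clustering,
p = (1 + #{I_perm ≥ I_obs})/(perms + 1)) is available. Isolated units are
an error — lag and Moran's I are undefined for them; an explicit flag on
row-standardization downgrades to zero rows with a warning.

## Spatial inequality (Dagum decomposition)

Overall Gini G = Σ_j Σ_h Σ_i Σ_r |x_ji − x_hr| / (2γn²) over the pooled
cross-section, decomposed by regional subgroups into G = Gw + Gnb + Gt
using the canonical within/between/transvariation split (formulas in the
`inequality` module docstring). The relative affluence D_jh is oriented by
the richer group so D_jh ∈ [0, 1]; ties across groups contribute zero to
both the affluence and transvariation integrals (measure-zero convention).
All intermediates (group means, shares, pairwise Ginis, D_jh) are exposed
in the result for audit. Regions are ordered (north, southwest, southeast)
so the pairwise columns of the yearly table have a stable order; the yearly
table carries a Mean row equal to the arithmetic column means.

## Determinants (panel regression)

The determinants model is log-log: Y_it = a_i + l_t + Σ_n γ_n X_itn + e_it
with Y the log index and five logged covariates (GDP, urbanization rate,
weighted passenger+freight transport volume, foreign-capital/GDP ratio,
tertiary-employment share), so slopes are elasticities. All variables are
logged; non-positive values are an ingest error (no offsets). Estimators:

- **Pooled OLS** with intercept.
- **Fixed effects** by within transformation; two-way uses exact double
  demeaning (valid on balanced panels) and equals LSDV to 1e−8 in tests.
  Degrees of freedom deduct the absorbed effects.
- **Random effects** by Swamy–Arora feasible GLS: σ²_e from the within
  regression, the unit-effect variance from the between regression
  (truncated at zero with a warning when negative), quasi-demeaning factor
  θ = 1 − sqrt(σ²_e/(Tσ²_u + σ²_e)). A Wald chi-square for the joint slope
  vector (df = 5) is reported.
- **Breusch–Pagan LM** for unit effects,
  LM = (nT/(2(T−1)))·[Σ_i(Σ_t e_it)²/Σ e² − 1]², with the one-sided
  boundary p-value (halved χ²(1) tail, the chibar²(01) convention).
- **Hausman** H = d′(V_FE − V_RE)⁺d over the five common slopes; a
  non-PSD variance difference falls back to the Moore–Penrose
  pseudo-inverse with a warning instead of failing.

Standard errors are conventional homoskedastic. The recovery harness
simulates panels from the two-way-effects DGP and refits; with n = 61,
T = 10, noise s.d. 0.05 and 100 replicates the mean recovery error per
coefficient is well below 0.01 (per-replicate sampling s.d. of a slope is
about 0.05/√540 ≈ 0.002).

## Synthetic data generator

The generator emulates the study shape, not any real region's statistics:

- **Units and regions:** 61 units in ordered contiguous blocks of 21/20/20
  (north, southwest, southeast) on an 8x8 queen-contiguity lattice (first
  61 cells, connectivity verified) standing in for county contiguity.
- **Indicator panel:** indicator j of unit i in year t is
  scale_j · (baseline_r + trend_r·(t−2010) + u_i + ε_ijt), with one SAR
  unit effect u = (I − ρW)⁻¹η shared across indicators (ρ = 0.6 by
  default) — a single spatial field keeps the composite index spatially
  autocorrelated, which is the property the mobility stage needs, without
  simulating 20 independent spatial processes. Defaults: regional
  baselines (1.7, 1.0, 1.3) and trends (0.09, 0.07, 0.08) per year, unit
  effect s.d. 0.25, indicator noise s.d. 0.20, deterministic per-indicator
  scales geometrically spread over [0.5, 5]. These were chosen once so the
  pooled Ci spans most of [0, 1] (the published pooled range runs 0.001 to
  0.956) with a visible regional gradient and strictly rising yearly
  means; they are a plausibility choice, not a calibration claim. The cost
  indicator is generated on a reversed latent scale (declining over time,
  low where supply is high). Values are clipped positive at 0.01.
- **Covariate panel:** X, unit effects and year effects standard normal;
  disturbance s.d. 0.05; true elasticity vector (0.165, 0.192, 0.295,
  0.094, 0.077).
- **Determinism:** all randomness flows through one
  `numpy.random.default_rng(seed)` Generator (PCG64), so a fixed config
  reproduces every output bit-for-bit.

What the generator does **not** emulate: real county adjacency and
geography, indicator-specific spatial fields, measurement error structure
of yearbook data, serial correlation in disturbances, or any calibration
to actual Zhejiang statistics. Passing tests therefore demonstrate that
the estimators and bookkeeping are correct under a controlled DGP, not
that any substantive finding about a real region is reproduced.

## Packaged published tables

Machine-readable copies of the published summary tables ship as fixtures:
the 20-indicator weight/direction system, the yearly global Moran table,
the yearly Gini decomposition series, and the transition-matrix layout.
Transition counts are not printed at count level; `derive_count_row`
recovers each row's integer composition by exhaustive search for counts
whose percentages round (half-up, 2 decimals) to the printed cells,
requiring uniqueness — e.g. the high-level row (n = 110) resolves uniquely
to (3, 5, 10, 92). These derived counts are labelled as such and are never
presented as printed data.

## Numerical conventions and degenerate inputs

- Quantiles: `numpy.quantile(..., method="linear")`, pinned.
- Row-stochasticity, Dagum additivity and the spatial-Markov partition
  identity are enforced/tested at 1e−12.
- Empty Markov rows: undefined (NaN), queried access raises.
- All-equal index values: every observation falls in level I (c ≤ Q1), with
  a degeneracy warning.
- Zero-variance cross-sections: Moran's I raises.
- Rounding is display-only; persisted pipeline outputs keep full precision
  (percent changes recomputed from rounded tables can differ in the last
  digit from pre-rounding computation, so the pipeline never rounds before
  deriving).

## Problem sizes used in the shipped checks

Test and acceptance runs use the study-sized panel (61 x 10), 100
Monte Carlo replicates for elasticity recovery, 500/200 null replicates
for the BP-LM and Moran-permutation calibration checks (199 permutations
per Moran test), and 200 random grouped samples (n ≤ 60, k ≤ 4) for the
Dagum oracle comparison; the full suite runs in a few seconds on one CPU.
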