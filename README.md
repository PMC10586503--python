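# supplyscape

Measurement and spatial-dynamics analysis of regional older-adult-service
supply from county-level panel data.

Public-health and regional-economics analysts who need to quantify how the
supply of older-adult care services is distributed across counties — and
whether that distribution is converging, clustering, or polarizing — face
the same chain of tasks: collapse a battery of heterogeneous service
indicators into one comparable index, describe how the index's
cross-sectional distribution evolves, test whether neighboring counties
move together, decompose the inequality into within- and between-region
parts, and regress the index on candidate determinants. `supplyscape`
implements that chain as a tested, reusable pipeline.

## The methods

- **Entropy-TOPSIS index.** Direction-aware min-max normalization of the
  county x year x indicator matrix, objective entropy weights
  ω_j ∝ 1 − e_j (e_j the column's normalized Shannon entropy), and the
  TOPSIS closeness coefficient C_i = D⁻/(D⁻ + D⁺) ∈ [0, 1], the distance
  ratio to the per-indicator worst/best ideal points of the weighted
  matrix. A packaged 20-indicator evaluation schema (four dimensions:
  social security, care service, health support, emotional comfort; one
  cost-type indicator) ships with published fixed weights as an
  alternative to entropy weighting.
- **Distribution dynamics.** Fixed-bandwidth Gaussian KDE
  (f(x) = (1/Nh) Σ K((X_i − x)/h), default h = 0.05) per year and region,
  with numerical extraction of main-peak position/height, peak count,
  curve width and tail masses.
- **Mobility.** Pooled-quartile classification into levels I–IV, maximum
  likelihood transition matrices P_ij = n_ij/n_i, spatial Markov matrices
  conditioned on the origin-year quartile of the spatial lag, and global
  Moran's I (E(I) = −1/(n−1)) with normality or permutation inference.
- **Inequality.** Dagum decomposition of the Gini coefficient,
  G = G_w + G_nb + G_t (within, net between, transvariation), exact to
  machine precision.
- **Determinants.** Log-log panel regression
  Y_it = a_i + l_t + Σ γ_n X_itn + e_it by pooled OLS, Swamy–Arora random
  effects and one-/two-way fixed effects, with Breusch–Pagan LM and
  Hausman specification tests and a Monte Carlo elasticity-recovery
  harness.
- **Synthetic studies.** A seeded generator of study-shaped inputs — 61
  counties in three regional blocks, years 2010–2019, queen-lattice
  adjacency, SAR-autocorrelated unit effects, known elasticities — so
  every stage can be exercised and validated without restricted data.

See `docs/methods.md` for formulas, defaults and design decisions.

## Worked example

```python
import supplyscape as ss

cfg = ss.SimConfig(seed=1)                      # 61 counties x 2010-2019
panel = ss.simulate_index_panel(cfg)            # 610 records x 20 indicators
weights = ss.make_lattice_weights(cfg)          # row-standardized queen lattice

index, wvec = ss.build_index_panel(panel)       # entropy-TOPSIS
print(index.head(3).round(4))
#  unit_id region_id  year  d_plus  d_minus     ci
#      c01     north  2010  0.0921   0.1344 0.5932
#      c01     north  2011  0.0824   0.1445 0.6367
#      c01     north  2012  0.0758   0.1520 0.6672

levels, scheme = ss.classify_levels(index)      # pooled quartiles, I-IV
matrix = ss.mle_transition_matrix(ss.count_transitions(levels))
print(matrix.frame().round(2))
#         n      I     II    III     IV
# I     150  79.33  20.67   0.00   0.00
# II    143   0.00  74.83  25.17   0.00
# III   134   0.00   0.00  74.63  25.37
# IV    122   0.00   0.00   2.46  97.54

print(ss.morans_i_by_year(index, weights).head(2).round(3))
#  year      I   E(I)  SD(I)      z    p stars
#  2010  0.472 -0.017  0.069  7.093  0.0   ***
#  2011  0.465 -0.017  0.069  6.989  0.0   ***
```

Reading the output: county c01's supply index rises 0.593 → 0.667 over
2010–2012 (the generator builds in upward trends). The transition matrix's
dominant diagonal (79–98% staying probabilities) is the "club convergence"
signature — counties tend to keep their capacity level year over year,
with essentially all movement one level upward. Moran's I ≈ 0.47 against a
null expectation of −1/60 ≈ −0.017 (z ≈ 7) says neighboring counties'
supply levels cluster strongly, as expected with spatial dependence
ρ = 0.6 built into the generator.

The same pipeline runs from the shell:

```sh
supplyscape simulate --out study --seed 1
supplyscape run --panel study/panel.csv --weights study/weights.gal \
                --covariates study/covariates.csv --out results
```

which writes every stage's table (index, KDE curves/features, Moran by
year, plain and spatial transition matrices, yearly Dagum decomposition,
regression and specification tests) plus a reproducibility manifest.

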