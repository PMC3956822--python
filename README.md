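# phylofid

Phylogenetic comparative analysis of flight-initiation distance (FID) — the
distance at which a bird flees from an approaching human — against the sizes
of brain components (brain stem, optic lobe, cerebellum, forebrain), whole
brain, eye size, body mass and starting distance, across a set of species
related by a phylogeny.

It is written for comparative biologists who want the full analysis chain as
a tested, scriptable package rather than a one-off analysis: phylogenetic
signal estimation, PGLS regression, allometric size correction, exhaustive
information-theoretic model selection, and repetition of everything over
competing phylogenetic hypotheses.

## The model

For trait vector **y** over *n* species, a rooted phylogeny with branch
lengths implies the Brownian-motion covariance matrix **C** (entry *(i,j)* =
shared root-to-MRCA path length). The regression model is

```
y = Xβ + ε,   ε ~ N(0, σ² V(λ)),   V(λ) = λC + (1−λ) diag(C)
```

where Pagel's λ ∈ [0, 1] multiplies the off-diagonal elements of **C**.
λ = 1 is full Brownian signal (equivalent to Felsenstein's independent
contrasts); λ = 0 removes all phylogenetic correlation (ordinary least
squares on an ultrametric tree). λ is estimated by maximum likelihood —
per trait for signal estimates, and from the residual errors of each
regression model for PGLS fits; a constrained λ = 1 mode reproduces an
independent-contrasts analysis.

Organ sizes enter models as *residual* sizes: observed log₁₀ size minus the
prediction of a PGLS regression of log size on log specimen body mass. All
subsets of {starting distance, body mass, residual eye size, four residual
brain components} plus whole-brain subsets (whole brain never together with
a component, since it is their sum) — 136 candidate models — are ranked by
AICc. Akaike weights give per-predictor cumulative weights w(+j) and
model-averaged coefficients with 95% CIs carrying between-model uncertainty;
these inferences are finally averaged arithmetically across phylogenies.

## Worked example

Generate a study-shaped synthetic dataset (41 species, five alternative
phylogenies, strong starting-distance and body-mass effects, a weak negative
cerebellum effect) and run the multi-phylogeny analysis:

```python
import phylofid as pf

table, trees, _ = pf.paper_shaped_fixture(seed=7)
summary = pf.run_ensemble(table, trees, mode="ml")
print(summary.pooled.round(3))
```

```
                 weight   coef     se  ci_low  ci_high
body_mass         1.000  0.301  0.036   0.230    0.372
brain_stem_res    0.166  0.037  0.273  -0.497    0.572
cerebellum_res    0.226 -0.268  0.302  -0.860    0.324
eye_res           0.290  0.430  0.432  -0.416    1.276
forebrain_res     0.270 -0.280  0.252  -0.774    0.214
optic_lobe_res    0.163 -0.022  0.263  -0.538    0.494
start_dist        1.000  0.548  0.122   0.308    0.787
whole_brain_res   0.152 -0.433  0.352  -1.122    0.256
```

The two generating predictors (starting distance, body mass) carry weight
≈ 1 with CIs excluding zero; every brain term has low weight, and the
cerebellum coefficient is negative (as simulated) with a CI spanning zero.
The ranked model table for one phylogeny shows the best models:

```python
print(summary.model_tables["base"].head(3)
      [["model", "delta_aicc", "weight", "lambda", "r_squared_pct"]]
      .round(2).to_string(index=False))
```

```
                                   model  delta_aicc  weight  lambda  r_squared_pct
                  body_mass + start_dist        0.00    0.19     0.0          73.64
body_mass + start_dist + whole_brain_res        1.27    0.10     0.0          74.57
  body_mass + forebrain_res + start_dist        1.45    0.09     0.0          74.46
```

Each row is one candidate model: its AICc distance from the best model,
Akaike weight, the residual-error λ estimated for that model (0 here: no
phylogenetic signal left once the predictors are in), and the whitened-space
R² in percent.

Single fits follow the usual model/results pattern:

```python
import numpy as np
tree = pf.simulate_tree(41, seed=1)
cov = tree.vcv()
rng = np.random.default_rng(0)
x = pf.simulate_trait(cov, 1.0, 1.0, 0.0, rng)
y = 0.5 * x + rng.normal(size=41)
fit = pf.PGLS(y, x, cov, exog_names=["mass"]).fit("ml")
print(fit.summary())
fit.plot_fit("mass")          # scatter + fitted line
```

The same pipeline runs from the shell on real files
(`phylofid run-all --traits table.tsv --tree composite.nex --tree ... --out-dir out/`),
consuming a TSV trait table (columns `species, fid_m, start_dist_m,
body_mass_g, specimen_mass_g, eye_volume, chiffre_basal_g, index_<region>`)
and Newick/NEXUS phylogenies, and writing the per-trait λ table, per-tree
ranked model tables, pooled inference tables and a manifest.
`phylofid simulate --seed 5 --out-dir data/` writes a synthetic dataset in
exactly that dialect.

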