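# clustvar

Clusterwise VAR(1) modeling of multivariate time-series panels.

Intensive longitudinal designs — daily diaries, experience sampling,
ambulatory assessment — yield one multivariate time series per person.  A
first-order vector autoregression (VAR(1)),

```
y_t = c + Φ y_{t-1} + u_t ,
```

captures each person's within-person dynamics: the M × M slope matrix Φ
holds autoregressive effects on its diagonal and cross-lagged effects off
it, and the innovations u_t are the contemporaneously correlated shocks.
When individual differences in these dynamics are *qualitative* — subgroups
of people share a dynamic regime — fitting one VAR per person wastes data
and fitting one VAR to everyone blurs the regimes.  `clustvar` takes the
middle road: it partitions the I persons into K clusters and fits **one
shared VAR(1) model per cluster**, choosing both jointly to minimize the
pooled squared one-step prediction error

```
L_K = Σ_i Σ_t ‖ y_it − ŷ_it ‖² .
```

Estimation is by alternating least squares (ALS): refit each cluster's
model on its members' concatenated data, reassign each person to the
best-predicting cluster (refitting the two affected models after every
move), repeat until the partition is stable.  Because the loss surface has
many local optima, the fit is launched from many random partitions plus one
"rational" start (Ward clustering of per-person VAR slopes), and the best
run is kept.  The number of clusters is chosen with the scree-test ratio
`st_K = (L_{K−1} − L_K) / (L_K − L_{K+1})` after a convex-hull filter.

The package is aimed at researchers analyzing person-level panels
(psychology, psychiatry, behavioral medicine) and at methodologists who
want to rerun or extend the method's factorial recovery studies.

## Worked example

```python
import numpy as np
import clustvar as cv

# a synthetic panel: 30 persons, 2 latent regimes, 6 variables, T = 100
cell = cv.DesignCell(K=2, T=100, I=30, similarity="highly_dissimilar",
                     size_regime="equal", innovation_regime="equal")
ds = cv.generate_dataset(cell, seed=42)


res = cv.multistart_fit(ds.panel, K=2, n_random_starts=20, rng_seed=7)
print(f"loss            {res.best.loss:.1f}")
print(f"attraction rate {res.attraction_rate:.2f}")
print(f"ARI vs truth    {cv.adjusted_rand(ds.true_partition, res.best.partition):.2f}")

dist = cv.coefficient_distance(ds, res.best, reference="generating")
print(f"coef distance   {dist.mean_distance:.3f}")
```

prints

```
loss            17829.9
attraction rate 1.00
ARI vs truth    1.00
coef distance   0.159
```

The attraction rate of 1.00 says every one of the 21 ALS runs reached the
same minimum loss — no local-optimum trouble on this easy instance;
ARI = 1 means the estimated partition equals the ground truth exactly; the
coefficient distance is the mean (over clusters) Frobenius distance between
the estimated slope matrices and the generating ones after the best label
matching — here pure sampling error at T = 100.

Model selection and interpretation on the same panel:

```python
series, fits = cv.select_k(ds.panel, 1, 6, n_random_starts=20, rng_seed=7)
print(series.selected_k)        # -> 2
q1, q2, q3 = cv.quartile_states(ds.panel)
path = cv.forecast(fits[2].best.models[0], q3, horizon=10)
r2 = cv.r_squared(fits[2].best.models[0], ds.panel.persons[0].segments)
```

`forecast` traces the innovation-free 10-step trajectory from a "high"
state (all variables at their third quartile) — how quickly a cluster
returns to baseline; `r_squared` gives the per-variable one-step explained
variance that distinguishes predictable ("rigid") from unpredictable
("flexible") clusters.

The same workflows are available from the shell:

```
clustvar preprocess --input raw.csv --id person --time day --gap 1 \
    --center --screen-modus 0.9 --output clean.csv
clustvar fit --input clean.csv --k 2 --random-starts 100 --seed 13 \
    --output fit.json
clustvar select-k --input clean.csv --k-min 1 --k-max 6 --seed 13 \
    --output scree.json
```

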