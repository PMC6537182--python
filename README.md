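# whogem

Admixture-based geolocation and quantitative-trait prediction for
structured plant (and other) populations.

## The problem

In wild, self-fertilizing species such as *Medicago truncatula*,
genetics and geography are tightly coupled: a sample's genome is a
mixture of a handful of ancestral gene pools, and that mixture changes
smoothly across the landscape (isolation by distance).  This package
turns that coupling into two prediction machines:

1. **Geolocation.**  A sample's genome-wide SNP dosages are summarized
   as a K-dimensional admixture vector θ (rows of the ADMIXTURE-style Q
   matrix, summing to one).  The Euclidean distance
   Δ_GEN between θ and a geo-referenced reference panel is converted to
   a geographic search radius through a calibrated linear
   isolation-by-distance relationship, Geo = a + b·Gen, fitted below a
   distance cutoff where the relationship is linear.  The predicted
   location is a weighted displacement (weights w_m = Δ_GEN^min /
   Δ_GEN(m), with exact ties pooled) from the best-matching unit's
   position, clipped to the radius.

2. **Trait prediction.**  Because the admixture vector integrates
   demography and local adaptation, quantitative traits — plant
   functional traits and quantitative disease resistance scores — are
   modelled as linear functions of the admixture components,
   y = β₀ + Σ β_k θ_k + ε, with a best-minimum-model search over
   component subsets (the simplex constraint makes the full model
   collinear) and an α = 5% retention benchmark.  Reliability is
   benchmarked against five genomic-selection baselines (RR-BLUP,
   G-BLUP, BayesB, RKHS, LASSO) under repeated stratified k-fold
   cross-validation with Kruskal–Wallis letter-group comparison.

The number of components K is chosen by three concordant criteria:
masked-entry cross-validation error of the admixture likelihood, a
k-means/BIC scan on PCA-reduced genotypes (the DAPC route), and the
parsimony rule "smallest K that geolocates as well as the best".

A first-class synthetic-data module generates seeded landscapes
(spatially anchored populations, distance-decay admixture,
Balding–Nichols allele frequencies, Q-linear traits, spatially
structured climate) so the entire pipeline is testable without any
download.

## Worked example

```python
import numpy as np, pandas as pd
from whogem.synthetic_data import LandscapeConfig, make_landscape, simulate_genotypes
from whogem.admixture_model import estimate_q_supervised
from whogem.provenance import (admixture_distance_matrix,
                               geographic_distance_matrix, calibrate,
                               loo_cross_validate)

cfg = LandscapeConfig(K=4, n_per_pop=50, n_loci=2000, fst_f=0.2,
                      decay_rho=1.5, seed=7)
geo, q_true = make_landscape(cfg)
G, _ = simulate_genotypes(q_true, cfg.n_loci, cfg.fst_f, seed=8)
labels = pd.Series(geo["population"].values, index=geo["sample_id"].values)
Q, F = estimate_q_supervised(G, labels)
print("mean |q_hat - q_true| =", round(float(np.abs(Q.theta - q_true.theta).mean()), 4))

genD = admixture_distance_matrix(Q.reorder(list(geo["sample_id"])))
geoD = geographic_distance_matrix(geo)
il = np.tril_indices(geoD.shape[0], -1)
cal = calibrate(genD, geoD, cutoff=float(np.quantile(geoD[il], 0.75)),
                n_perm=999, seed=9)
print(f"Mantel r = {cal.mantel_r_all:.3f} (p = {cal.mantel_p:.4f}); "
      f"Geo = {cal.intercept:.3f} + {cal.slope:.3f} x Gen (adj r2 = {cal.adj_r2:.2f})")
loo = loo_cross_validate(geo, Q, cal)
print(f"LOO median error = {loo.median_error:.2f} degrees; "
      f"country accuracy = {100*loo.country_accuracy:.1f}%")
```

Output:

```
mean |q_hat - q_true| = 0.0199
Mantel r = 0.797 (p = 0.0010); Geo = 1.348 + 5.726 x Gen (adj r2 = 0.68)
LOO median error = 1.27 degrees; country accuracy = 98.5%
```

Reading it: supervised admixture recovers the generating ancestry
vectors to ~0.02 mean absolute error; the Mantel test confirms strong
isolation by distance (r = 0.80, permutation p = 0.001); the fitted
line converts an admixture distance Gen into a geographic radius in
degrees; and leave-one-out validation places half of the samples within
1.3 degrees (~140 km) of their recorded location, with 98.5% assigned
to the correct country.

The calibration constants published for the real Mediterranean
*M. truncatula* panel (Geo = 0.204 + 4.973 × Gen below 950 km) ship as
`whogem.PAPER_CALIBRATION` for placing samples against externally
produced Q matrices.

A `whogem` console script exposes the same pipeline from the shell
(`whogem simulate`, `prune`, `admix`, `admix-cv`, `dapc`, `calibrate`,
`locate`, `loo`, `lsmeans`, `fit`, `predict`, `gs-fit`, `gs-predict`,
`benchmark`, `envassoc`, `rda`); every subcommand is a thin wrapper
over the library functions.

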