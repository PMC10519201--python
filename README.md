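# isoniche

Bayesian stable-isotope niche and stomach-content analysis of sympatric
species.

Coexisting predators that share a habitat are expected to partition
trophic resources.  `isoniche` quantifies that partitioning from two
complementary data sources — bulk muscle δ13C/δ15N values (long-term
assimilated diet) and stomach-content prey weights (recent diet) — for
groups structured by species, sex, maturity stage and season.  It was
built around three sympatric batoids of the southern Gulf of California
(*Hypanus dipterurus*, *Narcine entemedor*, *Rhinoptera steindachneri*)
but is generic over groups.

The workflow has four statistical stages:

1. **Hierarchical bivariate robust regression.**  Isotope pairs follow a
   bivariate Student-t, `(δ13C, δ15N) ~ StudentT₂(ν, α_s + Σ_f β_{s,f} x_f, Σ_s)`,
   with season/sex/stage slopes nested within species, partial pooling of
   intercepts, and Laplace ("Bayesian lasso") shrinkage on the slopes.
   Posteriors are sampled by MCMC with rank-normalized split R-hat and
   bulk-ESS convergence gates, and summarised by means, 95% highest
   density intervals and directional probabilities P(β ≷ 0).
2. **Isotopic niche areas.**  Per group, the Bayesian standard ellipse
   area SEA_B — the posterior of π·√det Σ — from a conjugate
   normal–inverse-Wishart fit, with small-sample correction
   SEA_c = SEA·(n−1)/(n−2) and posterior area comparisons.
3. **Directional niche overlap.**  The probability that an individual of
   species A lies inside the 95% probability region of species B's niche
   distribution, propagated over posterior uncertainty by Monte Carlo —
   asymmetric by construction.
4. **Diet classification.**  Balanced Random-Forest classifiers
   (undersampling + SMOTE, grid search, stratified 5-fold CV, 75–25
   train–test split, ROC AUC) with Shapley prey-importance attribution.

A synthetic-data module generates isotope and diet tables with the same
statistical structure (heavy-tailed bivariate isotope clouds, hurdle
log-normal prey weights), so the full pipeline runs and is tested without
any field data.  See `docs/methods.md` for the model, priors and design
choices.

## Worked example

Simulate a study-sized dataset and run the full pipeline:

```sh
isoniche simulate --seed 1 --out demo/
isoniche run --config examples/full_run.yaml --out demo/run --seed 1
```

or the equivalent in Python:

```python
from isoniche.synthetic_data import default_isotope_spec, generate_isotope_dataset
from isoniche.hier_model import HierModelConfig, fit_hier_mvst, species_mean_summary
from isoniche.niche_ellipse import fit_bivariate_posterior, sea_b

iso = generate_isotope_dataset(default_isotope_spec(), seed=12345)
post = fit_hier_mvst(iso, HierModelConfig(chains=3, warmup=1000, steps=1500,
                                          draws=3000, target_ess=200, seed=1))
print(species_mean_summary(post, force=not post.converged))
```

One acceptance run (`--seed 1`) printed, among other quantities:

| quantity | value |
| --- | --- |
| posterior mean δ13C, *H. dipterurus* | −15.77 ‰ |
| posterior mean δ15N, *N. entemedor* | 17.99 ‰ |
| SEA_B mean area, *H. dipterurus* | 7.63 ‰² |
| SEA_B mean area, *N. entemedor* | 2.08 ‰² |
| overlap, *R. steindachneri* in *H. dipterurus* | 99.3 % |
| overlap, *H. dipterurus* in *N. entemedor* | 7.6 % |
| test AUC, species diet classifier | 1.00 |
| test AUC, *N. entemedor* maturity stages | 0.83 |

Reading: the three species separate cleanly in isotope space
(*N. entemedor* most ¹³C-enriched, i.e. most benthic/infaunal;
*H. dipterurus* most depleted), *H. dipterurus* has by far the broadest
isotopic niche — so the narrow-niche species sit almost entirely inside
its niche while the reverse overlap is small — and stomach contents
separate the two species almost perfectly (driven by sipunculids and
polychaetes versus bivalves and stomatopods), with a clear ontogenetic
diet shift within *N. entemedor*.  Values fluctuate with the seed at
these sample sizes (n = 81/69/74 individuals per species).

## Command-line interface

```
isoniche simulate   --seed N --out DIR [--n-isotope N] [--n-diet N]
isoniche validate   --schema isotope|diet FILE
isoniche fit-hier   --data FILE --seed N --out DIR [sampling options]
isoniche niche      --data FILE --group-by species[,sex...] --out DIR
isoniche overlap    --data FILE --conf 0.95 --nmc 10000 --out DIR
isoniche classify   --data FILE --target species|sex|stage|season --out DIR
isoniche run        --config FILE --out DIR [--seed N] [--stages ...]
```
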