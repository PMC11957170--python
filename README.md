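# penbayes

Continuous Bayesian estimation of missense-variant **penetrance** — the
probability that a heterozygous carrier of a variant manifests disease —
for rare, incompletely penetrant conditions such as the inherited arrhythmia
CPVT (catecholaminergic polymorphic ventricular tachycardia) caused by
missense variants in the cardiac ryanodine receptor RyR2.

Classic variant classification (ACMG categories, ClinVar labels) answers
"is this variant disease-causing?" but not the clinically harder question
"what fraction of carriers will become ill?".  Most variants are seen in
one or two carriers, so their observed affected fraction is 0 or 1 and
nearly meaningless.  `penbayes` addresses this with empirical-Bayes
shrinkage and covariate calibration, for clinical geneticists, variant
curators and methodologists working with curated carrier-count tables.

## Model

For variant *i* with α*ᵢ* affected and β*ᵢ* unaffected heterozygotes:

* **Observed penetrance**  pᵢ = αᵢ / (αᵢ + βᵢ).
* **Evidence weight**  wᵢ = 1 − 1/(0.01 + nᵢ), nᵢ = αᵢ + βᵢ (clamped to
  [0, 1]): singleton reports carry ~0 weight, well-observed variants ~1.
* **Empirical prior**  Penetrance across variants is modelled as
  Beta(α₀, β₀).  The prior mean is the weight-normalized average
  Σ pᵢwᵢ / Σ wᵢ; the concentration ν = α₀ + β₀ is estimated from the
  ensemble's overdispersion by weighted beta-binomial marginal likelihood.
* **Empirical posterior**  Conjugacy gives
  (αᵢ + α₀) / (αᵢ + βᵢ + α₀ + β₀) per variant.
* **EM covariate calibration**  Variant-specific priors
  (α_EM,ᵢ, β_EM,ᵢ) with α_EM,ᵢ + β_EM,ᵢ = ν are obtained by iterating:
  weighted least squares of logit(posterior) on covariates (REVEL,
  AlphaMissense, binary-encoded ClinVar, structural disease density) →
  fitted means become new priors → posteriors recomputed, until the fitted
  means stop moving.
* **Bayesian posterior**  (αᵢ + α_EM,ᵢ) / (αᵢ + βᵢ + α_EM,ᵢ + β_EM,ᵢ),
  with equal-tailed beta credible intervals.  Variants never observed in a
  carrier keep their calibrated prior as a prospective estimate.
* **Structural disease density**  For each residue, the weighted affected
  fraction among heterozygotes of variants within a Cα–Cα radius (default
  15 Å) of it — a 3D hot-spot covariate, computable leave-one-variant-out
  to avoid self-leakage.
* **Hot-spot scan**  Sliding 100-residue windows with > 3 variants and
  mean penetrance > 0.4 over variant-bearing residues, merged into maximal
  segments.
* **Evaluation**  Brier score (mean squared forecast error), weighted
  Spearman rank correlation, ROC and precision–recall AUC with stratified
  bootstrap CIs, under leave-one-out and k-fold cross-validation.

## Worked example

```python
from penbayes import synthetic_data as syn
from penbayes import fit_empirical_prior, em_fit, bayesian_posterior

cfg = syn.SimulationConfig(n_variants=500, protein_length=200,
                           covariate_effects={"revel": 2.0}, seed=42)
data = syn.generate(cfg)          # counts, covariates, toy 3D structure
table = data.table

print(f"{len(table)} variants with observed heterozygotes")

prior = fit_empirical_prior(table)
print(f"empirical prior: mean={prior.mean:.4f}, nu={prior.nu:.2f} "
      f"(alpha={prior.alpha:.3f}, beta={prior.beta:.3f})")

model, priors = em_fit(table, prior, covariates=["revel", "cpvt_density"])
print(f"EM converged after {model.n_iterations} iterations; "
      f"revel slope={model.coefficients['revel']:+.3f}")

key = table.keys()[0]
rec = table[key]
est = bayesian_posterior(rec.counts, priors[key])
print(f"variant {rec.label}: {rec.counts.affected}/{rec.counts.total} "
      f"affected, prior={est.prior_mean:.3f}, "
      f"posterior={est.posterior_mean:.3f} "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
```

Output:

```
500 variants with observed heterozygotes
empirical prior: mean=0.1627, nu=1.69 (alpha=0.275, beta=1.414)
EM converged after 16 iterations; revel slope=+2.077
variant p.D100R: 0/19 affected, prior=0.022, posterior=0.002 [0.000, 0.021]
```

Reading it: across the ensemble the average penetrance is ~16%, but the
small concentration ν ≈ 1.7 says individual variants spread widely around
it.  The EM regression recovers a strong positive slope on the in-silico
score (the generating effect was +2 on the logit scale).  The example
variant was seen in 19 carriers, none affected, so its covariate-calibrated
prior (2.2%) is pulled down to a posterior of 0.2% with a tight credible
interval — a quantitative statement that this variant is, at most, very
weakly penetrant.

The same pipeline runs from the shell:

```sh
penbayes simulate --seed 7 --out run/sim
penbayes fit --variants run/sim/variants.csv --out run/fit
penbayes hotspot --estimates run/fit/estimates.csv --out run/hs
penbayes evaluate --variants run/sim/variants.csv --out run/eval
```

Real curated data enter through `penbayes ingest` (curated count table +
gnomAD-style population table, allele-frequency filter < 0.01% by default)
and `penbayes density` (mmCIF/PDB structure → per-variant structural
density).

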