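# hipca

Statistical health monitoring for the gut microbiome.

`hipca` turns a species-level relative-abundance table (MetaPhlAn2-style,
percent scale) into a quantitative **health index with a statistically
defined health boundary**, then explains any unhealthy call down to the
responsible species. It treats health prediction as multivariate statistical
process control: a PCA model is fitted to a *healthy* reference cohort only,
and any sample is scored by how far it departs from that healthy correlation
structure. The package is for microbiome researchers and method developers
who want an interpretable, unsupervised alternative to trained classifiers
for stool-metagenome health stratification.

## The model

Healthy-cohort abundances are transformed by

    lt(x) = log2(2x + sigma)   for x <= 1
    lt(x) = sqrt(x)            for x > 1

(σ a small offset keeping zeros finite), z-scored with parameters frozen on
the healthy training set, and decomposed by PCA of the sample covariance
S = XᵀX/(N−1). With loadings P (top *d* eigenvectors by cumulative explained
variance) and eigenvalues Λ, each sample **x** is scored by three control
charts:

- Hotelling **T²(x) = xᵀPΛ⁻¹Pᵀx**, monitoring the principal-component
  subspace, limit τ² = χ²α(d);
- **Q(x) = xᵀ(I − PPᵀ)x**, monitoring the residual subspace, limit
  δ² = (θ₂/θ₁)·χ²α(θ₁²/θ₂) with θₖ = Σᵢ>d λᵢᵏ;
- the combined health index **φ(x) = T²/τ² + Q/δ²**, limit ζ² = g·χ²α(h)
  where g = (d/τ⁴ + θ₂/δ⁴)/(d/τ² + θ₁/δ²) and h = (d/τ² + θ₁/δ²)²/(d/τ⁴ + θ₂/δ⁴).

φ is the health index reported to users (lower is healthier); a sample is
called unhealthy when φ exceeds ζ². When a sample alarms, the
**bacteria-to-health-index contribution** (BHC) of species *i* is the index
reduction achieved by optimally reconstructing the sample along that
species' direction,

    BHC_i = xᵀMξᵢ(ξᵢᵀMξᵢ)⁻¹ξᵢᵀMx,   M ∈ {PΛ⁻¹Pᵀ, I − PPᵀ, Φ},

with multi-species direction blocks supported through the pseudo-inverse.
Species panels are chosen by one-sided two-sample Kolmogorov–Smirnov tests
(health-scarce H− and health-prevalent H+ species), and healthy sub-patterns
are resolved by contrastive PCA — the eigenvectors of S_h − α·S_uh — with a
Gaussian-mixture model selected by AIC/BIC.

## Worked example

```python
import hipca

# synthetic cohort: 120 species, rank-8 healthy correlation structure,
# 500 unhealthy samples with a 6-sigma shift planted on one species
spec = hipca.SyntheticSpec(
    D=120, d_true=8, n_healthy=2000, n_unhealthy=500,
    zero_fraction=0.0, fault_species=[17], fault_magnitude=6.0, seed=0,
)
table, truth = hipca.generate_cohort(spec)

results = hipca.HiPCA.from_abundance(table).fit(pve=0.9, confidence=0.9)
print(results.summary())

scores = results.score(table.data, rule="combined")
report = hipca.evaluate_predictions(scores["decision"], table.metadata["label"])
print(f"balanced accuracy: {report.balanced_accuracy:.3f} "
      f"(TP {report.tp_rate:.3f}, TN {report.tn_rate:.3f})")

avg = hipca.population_bhc(results, table.subset("unhealthy").data, index="phi")
print("top contributor:", avg.iloc[0].idxmax(), "| planted:", truth.fault_species_ids)
```

prints

```
hiPCA monitoring model
==============================================
features (species):          120
training samples:            2000
retained components d:       8
explained variance:          0.9105 (target 0.9)
theta1, theta2:              10.7381, 1.3139
confidence (1 - alpha):      0.9
T2 limit tau2:               13.3616
Q limit delta2:              12.8609
phi limit zeta2:             1.8625

balanced accuracy: 0.950 (TP 1.000, TN 0.899)
top contributor: sp_0018 | planted: ['sp_0018']
```

The model recovers the true latent dimension (d = 8), the fitted limits sit
at the 90% χ² quantiles, every faulted sample is flagged (TP = 1.0) while
~10% of healthy samples exceed the boundary by construction (confidence
0.9), and the population-averaged contribution spectrum points at exactly
the planted species.

The same pipeline is available from the shell:

```sh
hipca simulate --spec spec.yaml --out-prefix sim
hipca fit --table sim.table.tsv --meta sim.meta.tsv --pve 0.9 --confidence 0.9 --out model.json
hipca predict --model model.json --table sim.table.tsv --out scores.tsv
hipca diagnose --model model.json --table sim.table.tsv --meta sim.meta.tsv --out-prefix diag
hipca patterns --model model.json --table sim.table.tsv --alpha auto --out patterns.tsv
hipca evaluate --scores scores.tsv --meta sim.meta.tsv --out eval.tsv
```

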