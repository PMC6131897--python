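# pureqtl

Cell-type-aware *cis*-eQTL mapping from heterogeneous bulk tumor expression.

## The problem

Solid-tumor biopsies are mixtures of cancer cells and tumor-associated normal
cells (immune, stromal, epithelial). Expression QTLs mapped from bulk tumor
expression therefore reflect regulatory variation in *all* of those cell
types, and an eQTL that acts only in the normal compartment can be
misattributed to cancer. `pureqtl` is for statistical geneticists and cancer
genomics analysts who want to know which tumor eQTLs can actually be
attributed to cancer cells, given per-sample tumor-purity estimates (e.g.,
consensus purity estimates from copy number, expression, methylation and
staining).

## The models

For each SNP–gene pair, with expression *y*, minor-allele dosage *x* ∈
{0, 1, 2} and optional covariates (genotype principal components **a**,
expression-heterogeneity factors **b**):

- **Conventional model** — the standard bulk scan:

  *y* = β₀ + β₁·*x* + **β₂·a** + **β₃·b** + ε

  β₁ is the eQTL effect in the tumor as a whole; significance is a two-sided
  *t* test on β₁.

- **Interaction model** — let *p* be the tumor-associated **normal**-cell
  fraction (*p* = 1 − purity, so *p* = 0 means 100% cancer cells):

  *y* = β₀ + β₁·*x* + **β₂·a** + **β₃·b** + β₄·*p* + β₅·(*p*·*x*) + ε

  Because the genotype effect is allowed to vary linearly with cell
  composition, the main effect β₁ is the eQTL effect extrapolated to a pure
  cancer-cell sample; β₅ measures how the effect differs between the two
  cell types. Cancer eQTLs are called by testing β₁.

- **Effect-difference test** — to compare an effect between two cohorts or
  tissues: *z* = (β₁ᴬ − β₁ᴮ) / √(SEᴬ² + SEᴮ²), two-sided normal p-value.

Multiple testing uses Benjamini–Hochberg FDR throughout.

The package also ships a full simulation framework that builds latent
cancer/normal expression with a known eQTL architecture (six groups: shuffled
effects, cancer-only, normal-only, no eQTL, shared, shared-with-noise),
mixes the compartments per sample with the cancer-cell fraction, degrades
the purity measurements with distribution-preserving noise, and scores any
scan against the simulated truth — so false-discovery control can be
validated under known conditions.

## Worked example

```python
from pureqtl import (SimConfig, simulate_cohort, add_purity_noise,
                     run_scan, classify_performance)

cohort = simulate_cohort(SimConfig(seed=1))          # 600 genes, 1000 samples
measured = add_purity_noise(cohort.purity, 0.1, seed=2)

conv = run_scan(cohort.bulk, cohort.genotypes, cohort.pairs, model="conventional")
inter = run_scan(cohort.bulk, cohort.genotypes, cohort.pairs,
                 purity=measured, model="interaction")
print(classify_performance(conv, cohort.truth).as_dict())
print(classify_performance(inter, cohort.truth).as_dict())
```

Running this (it is `examples/map_cancer_eqtls.py`) prints:

```
conventional model (377 calls at q<0.05):
  sensitivity  81.5%   specificity  74.5%   true FDR  13.5%
  false discoveries driven by normal-cell eQTLs: 49 of 51
interaction model (235 calls at q<0.05):
  sensitivity  57.5%   specificity  97.5%   true FDR   2.1%
  false discoveries driven by normal-cell eQTLs: 3 of 5
```

The conventional scan nominally controls FDR at 5% but its *realized* FDR
against the simulated cancer-eQTL truth is ~13%, almost entirely normal-cell
eQTLs leaking through the mixture. The interaction model gives up some
sensitivity (it extrapolates to a cell state never directly observed) but
keeps the realized FDR below the nominal level.

The `examples/` directory has one short script per capability: cohort
simulation, model comparison, purity-bin effect deconstruction, the
purity-noise robustness sweep, cross-cohort effect comparison, and
preprocessing/purity transfer.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
pureqtl simulate --out-dir sim --seed 1 --extra-normal-only 500
pureqtl map --expr sim/bulk_expression.tsv --geno sim/genotypes.tsv \
            --pairs sim/pairs.tsv --purity sim/purity.tsv \
            --model interaction --out results.tsv
pureqtl evaluate --results results.tsv --truth sim/truth.tsv
pureqtl sweep --seed 1 --out sweep.tsv
pureqtl zdiff --results-a a.tsv --results-b b.tsv --out z.tsv
pureqtl pipeline --config run.yaml
```

All matrices are TSV (features in rows, samples in columns); genotypes can
also be read from a minimal VCF. Every output carries a header comment with
the package version, seed and config hash.

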