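# landgen

A landscape-genomics analysis pipeline for diploid SNP data: population
diversity and differentiation statistics, windowed linkage-disequilibrium
decay fitting, and generalized dissimilarity modelling (GDM) of isolation by
distance and environment — together with a synthetic landscape/genotype
generator with known ground truth so every stage can be tested offline.

## Modules

| module | contents |
| --- | --- |
| `landgen.synthdata` | spatially structured landscape simulator (IBD + IBE on the logit-frequency scale), Gaussian-field environment generator with noise decoys, founder-mosaic linked-haplotype simulator, analytic LD-decay test curves |
| `landgen.genio` | VCF 4.2 (GT) reader/writer, locality/environment CSV, cross-table validation |
| `landgen.popgen` | Nei gene diversity (H_e), nucleotide diversity, Weir–Cockerham F_ST, genomic relationship matrix, Gower distances, PCA, Mantel test, haversine distances |
| `landgen.lddecay` | overlapping genomic windows, composite r², Hill–Weir decay-curve fitting, half-maximal-r² distances and summaries |
| `landgen.gdmcore` | monotone I-spline bases, site-pair tables, non-negative binomial-deviance GDM fitting, prediction, deviance explained |
| `landgen.gdmselect` | category-wise forward selection, permutation importance, backward selection, locality jackknife, locality cross-validation, whole-model permutation test |
| `landgen.pipeline` | config-driven orchestration with manifests |

## Command line

All functionality is reachable through the `landscape-dissim` entry point:

```bash
# simulate a landscape with strong IBD and one causal environmental variable
landscape-dissim simulate landscape --n-localities 39 --n-per-locality 6 \
    --n-loci 2000 --sigma2-geo 1 --phi-geo 300 \
    --sigma2-env 3 --phi-env 1.5 --causal precip_ann --seed 1 --out sim/

# windowed LD decay
landscape-dissim ld-decay --vcf sim/genotypes.vcf --window 30000 --overlap 10000

# geography-only GDM and full selection workflow
landscape-dissim gdm fit --vcf sim/genotypes.vcf --locality sim/localities.csv \
    --env sim/environment.csv --predictors geo
landscape-dissim gdm select --vcf sim/genotypes.vcf --locality sim/localities.csv \
    --env sim/environment.csv --seed 1

# config-driven runs (ibd | ibe | diversity | ld)
landscape-dissim run --config run.yaml --stage ibe
```

A minimal `run.yaml`:

```yaml
out_dir: out
simulate:
  n_localities: 20
  n_per_locality: 6
  n_loci: 2000
  ibd: {sigma2: 1.0, phi: 300.0}
  ibe: {sigma2: 3.0, phi: 1.5, causal_ids: [precip_ann]}
seed: 1
```

## Conventions

* Dosages are diploid alternate-allele counts {0, 1, 2}; missing (including
  half-calls) is NaN; statistics use pairwise-complete observations.
* VCF positions are 1-based; window arithmetic is 0-based half-open.
* Genetic distance fed to GDM is the Gower transform of the genomic
  relationship matrix (a squared-Euclidean quantity, as printed; a
  square-root flag exists on `gower_distance`).
* Every stochastic routine takes an explicit integer seed and is
  reproducible bit-for-bit.
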