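# hybeco

Hybrid-zone ecomorphology toolkit for two hybridising freshwater fish
species (labelled **Cn** and **Pt**). The package implements, as a tested
reusable pipeline:

- **`hybeco.simulate`** — synthetic hybrid-zone datasets (codominant
  genotypes, mtDNA, covariates, 21-landmark shapes, prey detections) with
  known ground truth, fully determined by a seeded configuration.
- **`hybeco.genetics`** — per-individual hybrid index `h ∈ [0, 1]` by
  maximum likelihood under a per-allele mixture model, three-class genomic
  assignment (`Cn` for h in [0, 0.086], `Pt` for h in [0.934, 1], `Hybrid`
  otherwise) with an mtDNA-discordance override, and Genepop I/O.
- **`hybeco.condition`** — condition coefficient `K = weight(mg)/size(cm)³`
  with outlier flags (K<5 or K>20), the AIC-selected
  `env × basis(size, m) × sp` trait model with type-III tests, the
  h-mixture prediction for hybrids and the `D = env × size × h` deviation
  model, and age-adjusted size comparisons (ANCOVA).
- **`hybeco.morpho`** — TPS landmark I/O, generalized Procrustes alignment
  (canonical orientation, reflection-free), per-coordinate trait models over
  the 42 aligned coordinates, deformation fields with BH-adjusted tests, and
  the hybrid-shape additivity test.
- **`hybeco.diet`** — gut-vacuity logistic model
  `logit P = h × (season + size + env)`, the first-axis PCA feeding index on
  prey compositions, the deterministic 3-class diet rule
  (invertebrate eater / omnivore / diatom eater), and the baseline-logit
  multinomial diet model.
- **`hybeco.pipeline`** — orchestration of all stages with input validation,
  stage logging, and byte-identical reruns under a fixed seed.

## CLI

```sh
hybeco simulate --seed 1 --out data/            # synthetic dataset
hybeco hybrid-index --geno data/genotypes.gen \
    --ref-cn pop1 --ref-pt pop2 --out out/      # h + genomic classes
hybeco condition --data data/ --out out/        # K model + additivity test
hybeco morpho --tps data/landmarks.tps \
    --covariates data/covariates.csv --out out/ \
    --compare sp:Cn,Pt --at-size median         # GPA + deformation field
hybeco diet --prey data/prey.csv \
    --covariates data/covariates.csv --out out/ # diet models
hybeco run --seed 1 --out run/                  # full pipeline
hybeco report --run-dir run/                    # re-render the report
```

`hybeco run` accepts `--config run.yaml` (see `hybeco.pipeline.RunConfig`
for the fields: thresholds, alpha, multiplicity adjustment, evaluation size
policy, stage toggles, simulation parameters or input paths).

## Data formats

All inputs and outputs are plain text: Genepop genotypes (2- or 3-digit
allele coding), TPS landmark files, and delimited CSV tables (covariates:
`id, station, zone, season, species, mtdna, age, size_cm, weight_mg, feces`;
prey: `id` + 8 binary item columns).
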