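# ftx

Muscle-aging functional transcriptomics toolkit. Reimplements, as a tested
and reusable pipeline, an analysis linking age-related skeletal-muscle
gene-expression changes to a composite physical-function score in mice:

- **`ftx.cfab`** — composite function (CFAB) scoring: five functional-test
  determinants standardized to a young reference group (inverted cling on
  the log10 scale) and summed; one-way ANOVA with LSD post hoc tests.
- **`ftx.diffexpr`** — from-scratch negative-binomial differential
  expression: median-of-ratios size factors, trend-shrunk
  method-of-moments dispersions, per-gene NB GLM (log2 link) fit by IRLS,
  Wald tests, Benjamini–Hochberg adjustment, log2-normalized counts, PCA,
  heatmap/fold-change helpers. DEG = padj < 0.05 and |log2fc| ≥ 1.
- **`ftx.association`** — per-DEG linear regression of normalized log2
  expression against CFAB, each determinant, and muscle (TA) mass, with
  strength (|R| ≥ 0.50 moderate, ≥ 0.70 strong), direction, and
  regulation labels plus a cross-tabulation.
- **`ftx.enrichment`** — fixed-threshold hypergeometric over-representation
  (enrichment ratio E, BH q-values) and preranked GSEA (weighted running
  sum, gene-label permutation null, NES/FDR), intersected over the DEG
  list.
- **`ftx.simulate`** — synthetic-study generator with known ground truth:
  three age groups (7/7/8 animals), two sequencing runs with re-prepared
  reference libraries, NB counts with an age-dependent DE fraction, and a
  latent per-animal function value coupled to a subset of DE genes.
- **`ftx.pipeline` / `ftx.cli`** — TSV/CSV/GMT IO, YAML config, manifest
  with checksums, and the `ftx` command-line driver.

## Command line

```sh
ftx simulate --seed 1 --outdir sim            # synthetic study + gene sets
ftx cfab --metadata sim/metadata.tsv --out scores.csv
ftx de --counts sim/counts.tsv --metadata sim/metadata.tsv \
       --contrast 6m:28m --out de.csv
ftx associate --counts sim/counts.tsv --metadata sim/metadata.tsv \
              --de de.csv --phenotype cfab --phenotype vwr --out assoc.csv
ftx enrich --de de.csv --gmt sim/gene_sets.gmt --nperm 1000 --seed 7
ftx run --counts sim/counts.tsv --metadata sim/metadata.tsv \
        --gmt sim/gene_sets.gmt --outdir results
```

`ftx run` executes the full chain (CFAB → DE → association → enrichment →
intersection) and writes every stage's table plus a `manifest.json` with
SHA-256 checksums; reruns with the same config are byte-identical.

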