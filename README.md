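# genefp

Literature-derived **gene-enrichment fingerprints** for diseases, and a
pipeline that infers disease–disease associations from them.

Each disease is represented by the set of genes over-represented in its
annotated literature: for every co-occurring gene a hypergeometric
enrichment p-value is computed from the (gene, disease) co-occurrence
counts, and the gene is weighted by `-log10(p)`. The per-disease
fingerprints are assembled into a disease × gene weight matrix, filtered
(genes tied to a single disease are dropped; diseases with too few genes can
be dropped), approximated by a truncated SVD under a 95%-energy rank rule,
converted to a Spearman-correlation distance matrix, and clustered with a
spectral clustering algorithm. Diseases sharing the query disease's cluster
are called *related*; hyperparameters (energy mode/target or explicit rank,
number of clusters, minimum fingerprint size) are tuned against expert
labels by grid search on precision/recall/F1, and the tuned model is used to
classify diseases whose expert label is undefined.

A synthetic corpus generator with planted disease clusters makes the whole
pipeline testable offline, end to end, with known ground truth.

## Library layout

| module                 | contents |
|------------------------|----------|
| `genefp.corpus_io`     | readers/writers for gene2pubmed TSV, (pmid, descriptor) TSV, MedlineCitation XML, vocabulary-tree TSV; branch selection; corpus assembly |
| `genefp.fingerprint`   | hypergeometric PMF / upper-tail enrichment p-values, per-disease fingerprints, highly-relevant-gene selection |
| `genefp.matrix_builder`| disease × gene matrix with the shared-gene and min-gene filters (fixed-point application) |
| `genefp.lowrank`       | deterministic SVD, energy-based rank selection (`sum` or `sum_of_squares`), reconstruction |
| `genefp.association`   | Spearman distances, normalized-Laplacian spectral clustering, `run_pipeline` |
| `genefp.evaluation`    | expert-vote aggregation, precision/recall/F1 scoring, grid-search `tune`, `predict_undefined` |
| `genefp.synthetic`     | planted-cluster corpus generator and label synthesis |
| `genefp.cli`           | `genefp` command-line entry point |

## CLI

```sh
# generate a synthetic corpus with planted clusters + expert labels
genefp simulate --seed 7 --out sim/

# full pipeline for one query disease
genefp associate \
    --gene2pubmed sim/gene2pubmed.tsv --disease2pubmed sim/disease2pubmed.tsv \
    --mesh-tree sim/mesh_tree.tsv --branch C99 \
    --query D900000 --k 3 --energy 0.95 --energy-mode sum_of_squares \
    --seed 7 --out assoc.json

# tune hyperparameters against expert labels, then classify the undefined ones
genefp tune --grid grid.yaml --query D900000 --labels sim/labels.tsv \
    --gene2pubmed sim/gene2pubmed.tsv --disease2pubmed sim/disease2pubmed.tsv \
    --mesh-tree sim/mesh_tree.tsv --branch C99 --seed 7 --out tuned.json
genefp predict-undefined --best-config tuned.json --query D900000 \
    --labels sim/labels.tsv --gene2pubmed sim/gene2pubmed.tsv \
    --disease2pubmed sim/disease2pubmed.tsv --mesh-tree sim/mesh_tree.tsv \
    --branch C99 --out predictions.json
```

Other subcommands: `build-fingerprints`, `build-matrix`, `approximate`,
`evaluate`. Every command writes a `<out>.meta.json` beside its output
(config echo, input checksums, version — no timestamps, so reruns are
byte-identical). Real data uses NCBI gene2pubmed and MeSH-derived inputs;
the disease branch (e.g. `C08.384`) is always an explicit parameter.

## Tests and acceptance report

```sh
python -m pytest -q tests/          # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the reportable targets (the F scores
implied by the published precision/recall pairs, on the percent scale) with
the package's scoring code and writes them as JSON.
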