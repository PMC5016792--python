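# vesnet

Analysis pipeline for microvesicle (MV) proteomics with network-based
functional interpretation.  Mesenchymal-stem-cell microvesicles carry a
protein cargo whose composition shifts when the cells are stimulated
(e.g. by brain-tissue extract); `vesnet` provides the computational
stages needed to characterise such proteomes from per-batch
spectral-count tables:

1. **Proteome assembly** — apply the inclusion rule (spectral count > 1
   in ≥ 1 batch, identification FDR < 0.01), classify proteins by
   batch-presence tier (≥ 1, ≥ 2, all batches), collapse proteins to
   genes, and compare proteomes between conditions.
2. **Vesicular-database coverage** — fraction of each tier annotated in
   a Vesiclepedia-like vesicular protein set, against random-sampling
   baselines.
3. **Differential abundance** — a Poisson likelihood-ratio test on
   spectral counts with per-batch size factors,
   LR = 2[ℓ(λ̂ₜ, λ̂꜀) − ℓ(λ̂₀)] with closed-form MLEs λ̂ = Σc/Σs and
   p from χ²₁, Benjamini–Hochberg FDR, and pseudocounted log₂ fold
   changes.
4. **Network coherence** — are the upregulated genes more connected in
   a gene network (HumanNet/HPRD-style edge list) than chance?  Two
   statistics — within-group edge count and shared-neighbour pair
   count — against M random equal-size gene sets, with add-one
   empirical p = (1 + #{null ≥ obs})/(M + 1).
5. **Module network** — filter the proteome by four functional
   categories (angiogenesis, anti-inflammation, neurogenesis,
   apoptosis; GMT input), test each category's hypergeometric
   enrichment, project onto the network, label components, and annotate
   nodes with upregulation and fold change; GraphML export.

A first-class synthetic-data module generates every input with known
ground truth (planted network modules, planted count upregulation,
exact-overlap annotation sets), so all operating characteristics are
measurable end to end.  See `docs/methods.md` for the models and their
assumptions.

## Worked example

Generate a synthetic study (300 proteins, 30 truly upregulated at rate
ratio 8, three batches per condition, a 1,000-node background network
with the up-genes planted as a dense module) and run the full pipeline:

```sh
vesnet simulate --out demo/fix --seed 7 --n-proteins 300 --n-up 30
vesnet pipeline --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
identifications: demo/fix/identifications.tsv
network: demo/fix/network.tsv
categories_gmt: demo/fix/categories.gmt
vesicle_gmt: demo/fix/vesicles.gmt
out_dir: demo/results
seed: 7
null_samples: 1000
```

The run logs each stage (`inclusion filter: 1800 -> 1710 rows`,
`285 proteins tested, 30 up genes`) and writes
`demo/results/coherence.tsv`:

```text
         statistic  set_size  observed  null_mean  null_sd         z        p
within_group_edges        30     189.0      4.270 2.085533 88.576861 0.000999
 neighbour_overlap        30     385.0     41.894 8.916068 38.481763 0.000999
```

The 30 upregulated genes share 189 edges where random 30-gene sets
average 4.3 — the planted module is recovered at the minimal empirical
p = 1/(M+1) = 1/1001 for both statistics.  `vesicular_coverage.tsv`
shows 80.4% of the ≥ 1-batch tier annotated as vesicular versus a
38.0% random baseline (p = 1/1001), and `modulenet_summary.json`
reports the module network (102 genes selected by the four categories,
46 connected by 43 links) and its enrichment for upregulated genes
(10 of 46 network genes upregulated vs 30 of 285 proteome genes,
one-sided hypergeometric p = 0.011).  Every results directory includes
a `manifest.json` with the seed, thresholds and SHA-256 digests of the
inputs; rerunning with the same config and seed reproduces all outputs
byte for byte.

The same stages are available as library functions
(`vesnet.assembly.assemble_proteome`, `vesnet.diffabund.call_deps`,
`vesnet.coherence.coherence_test`, ...) and as the subcommands
`simulate`, `assemble`, `enrich`, `diffabund`, `coherence`,
`modulenet`, `pipeline`.

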