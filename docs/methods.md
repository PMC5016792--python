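# Methods

`vesnet` re-implements, as a reusable and tested pipeline, the
computational analysis applied to mesenchymal-stem-cell microvesicle
(MSC-MV) proteomes after brain-extract treatment: multi-batch proteome
assembly from spectral-count identification tables, vesicular-database
coverage with random-sampling baselines, spectral-count differential
abundance, gene-set network-coherence testing against random-set nulls,
and construction of a GO-filtered module ("therapeutic") network.  A
synthetic-data module generates every input with known ground truth, so
each stage's operating characteristics are measurable without the
study's raw mass-spectrometry data.

## Proteome assembly

Input is a per-batch protein identification table (protein id, gene id,
condition, batch, spectral count, identification FDR).  The inclusion
rule keeps a protein within a condition iff its maximum spectral count
over batches is at least `min_spectral_count` (default 2, the strict
reading of "more than one spectral count in at least one batch") and
its best (minimum) identification FDR across batches is below
`inclusion_fdr` (default 0.01).  Per-batch *presence*, used for tiers,
is count ≥ 1: the inclusion threshold gates entry to the proteome, the
presence threshold classifies reproducibility.  Using a single
threshold for both roles would make the published tier counts
(cumulatively 1,523 / 921 / 591 proteins over one, two and three
batches) impossible to nest, so the two thresholds are separate config
keys.  Proteins observed in only some batches carry explicit zero
counts for the rest; absence and zero are not distinguished downstream.
Genes collapse many-to-one from proteins (one gene per protein enforced
at parse time); a gene occupies a tier iff at least one of its proteins
does.

Because the study's supplementary protein lists are not distributed,
the tier arithmetic is exercised on a deterministic synthetic
reconstruction (`tiered_identification_table`) that realises exactly
the published tier structure — 602/330/591 proteins present in exactly
one/two/three batches over 301/154/320 genes — with synthetic
identifiers.  This verifies the assembly arithmetic, not the original
identifications.

## Statistics

* **Enrichment** is the hypergeometric upper tail
  P(X ≥ k) for k of n query genes falling in a category of size K drawn
  from a universe of size N, equal to the one-sided Fisher's exact test,
  evaluated through `scipy.stats.hypergeom.sf` (log-space survival
  function).  The universe N must always be passed explicitly: a
  genome-wide versus an annotated universe changes p-values by orders
  of magnitude, and the published analyses do not state which was used,
  so the package refuses to default silently.  A pipeline run derives N
  from a declared policy (union of network nodes, proteome genes and
  category members) and records it in the output summary.
* **Multiple testing** uses Benjamini–Hochberg step-up adjusted
  p-values (`scipy.stats.false_discovery_control`); the original work
  names only "an FDR threshold of 0.01", and BH is the standard,
  assumption-light choice.
* **Empirical permutation p-values** use the add-one estimator
  p = (1 + #{null ≥ obs}) / (M + 1); ties count against the observed
  value, so p is never 0 and the test is conservative under heavy ties.
* **Correlation** is the product-moment r (and r²) with degenerate
  (constant) vectors rejected.

## Differential abundance

The published analysis delegated differential-expression calls to the
Bayesian spectral-count tool qprot, for which no settings are recorded
beyond the FDR threshold.  `vesnet` instead implements a self-contained
Poisson likelihood-ratio test whose operating characteristics are
verifiable by simulation.  Counts in condition g, batch i are modelled
as Poisson(λ_g·s_i) with size factors s_i = batch total / median batch
total.  The MLEs are closed-form (λ̂ = Σcounts/Σsizes), giving
LR = 2[ℓ(λ̂_t, λ̂_c) − ℓ(λ̂_0)] and a p-value from the χ²(1) survival
function.  BH q-values at q ≤ 0.01 (default) define DEPs; log2 fold
change is log2[(rate_t + c)/(rate_c + c)] with pseudocount c = 0.5 so
presence/absence proteins get finite, plottable fold changes.  Proteins
absent from one condition enter with zero counts in all its batches.
Batch pairing is not assumed; the two conditions may have different
batch counts.

Calibration and power, measured by the test suite and the acceptance
script on the generator's output: type-I error at α = 0.05 within
±0.02 over 5,000 null proteins; under a pure null the q ≤ 0.01 fraction
stays below 0.02; on the planted simulation (500 proteins, 50 with a
true rate ratio of 8, mean control count 10, three batches per side,
Poisson counts) sensitivity ≥ 0.9 and realized false-discovery
proportion ≤ 0.05 over 20 replicates.  These runs use dispersion 0 —
the matched case for a Poisson test.  With overdispersed counts (the
generator's general default, dispersion 0.1) the χ² reference is
anticonservative and the realized FDP rises; a quasi-likelihood or
negative-binomial test would be the remedy and is out of scope.  This
is the main known limitation.

## Network coherence

Two integer statistics quantify how connected a gene set s is in an
undirected network: the **within-group edge count** (edges with both
endpoints in s) and the **network-neighbour overlap**.  The latter is
not defined precisely in the source analysis; here it is fixed as the
number of unordered pairs {i, j} ⊆ s sharing at least one common
neighbour other than i and j themselves.  This pair-count is
integer-valued, oracle-checkable by brute force, and monotone under
growing s; a weighted variant (sum of neighbourhood Jaccard indices)
is available behind a flag.

The null is M random gene sets (default M = 1000) of exactly the
mapped size |s ∩ nodes| — genes missing from the network are dropped
*before* sizing the null, so poor identifier mapping is never rewarded.
The null universe defaults to all network nodes; a user-supplied
background (e.g. all detected genes) is supported because the two
choices calibrate differently and the source analysis does not say
which it used.  A degree-matched sampler (degree-decile bins) is
optional and off by default, mirroring the equal-size uniform null.
Each statistic draws its null from an independent substream
(`numpy.random.SeedSequence` spawn keys) of the master seed, so adding
a statistic never perturbs another's null.  The reported p is the
add-one empirical upper tail; the z-score uses the null mean and SD
(z = 0 when the null is degenerate at the observed value).

Calibration uses sets of size 30 on an Erdős–Rényi G(400, 0.05)
background: with this geometry the edge-count null has wide integer
support, so tie-induced conservatism stays small and the rejection rate
at α = 0.05 over 1,000 trials falls inside the exact binomial 99%
interval around the attainable level ⌊0.05(M+1)⌋/(M+1).  Power is
checked with planted modules (size 20, within-density 0.5 added to a
G(300, 0.01) background): the test returns the minimal p = 1/(M+1) in
≥ 95% of 100 replicates.

## Module network

Proteome genes are filtered by four user-supplied category sets
(angiogenesis, anti-inflammation, neurogenesis, apoptosis, as GMT; the
term-to-category curation is the user's, since the original mapping is
not enumerated).  Each category is tested for enrichment against the
explicit universe, BH-adjusted across the four tests.  The selection is
projected onto the gene network as an induced subgraph; isolated
selected genes are retained as singleton components so both published
ways of counting — "genes connected by links" versus the largest
component — are computable from the same output (the source text gives
both 247/1,439 and 236/1,276 for these, an unresolved internal
discrepancy, so the package emits both statistics and targets neither).
Nodes carry per-category boolean flags and fractional weights (flags
normalised to sum to 1), an upregulation flag, and the maximum |log2FC|
over the gene's upregulated proteins.  Enrichment of the module network
for upregulated genes uses query = connected network genes,
category = upregulated genes, background = proteome genes (both query
and category are proteome-conditioned); the query policy is
configurable ("all", "connected", "largest").

GraphML export sorts nodes and edges, writes nullable attributes with
an explicit "NA" marker (recorded per key so re-import restores floats
and Nones exactly), and round-trips identically.

## Synthetic data

* **Networks**: Erdős–Rényi G(n, p) or Barabási–Albert preferential
  attachment; planted modules add absent within-pair edges with the
  stated density and never remove edges.
* **Counts**: gamma-Poisson (negative binomial) with
  Var = μ + φμ², so φ = 0 recovers Poisson exactly; defaults are three
  batches per condition, mean count 10, dispersion φ = 0.1, 500
  proteins of which 50 are upregulated at rate ratio 8 — matching the
  three-batch design and the planted-signal recovery conditions used
  throughout.  A 5% decoy fraction draws identification FDRs above
  0.01 so the inclusion filter has nontrivial work.
* **Annotations**: sets with exact designed overlap (k members inside
  the query, K − k fillers outside), making enrichment counts
  integer-exact downstream.
* **Paired arrays**: y = r·x + √(1−r²)·ε on standard normals; the
  default (n = 90, r = 0.938) emulates a 90-protein cytokine-array
  comparison whose sample r² fluctuates around 0.88.

All generators are pure functions of their parameters and a seed under
numpy's PCG64 (`default_rng`), so fixtures are reproducible bit-for-bit
across platforms; the pipeline itself is byte-deterministic under a
fixed seed (sorted outputs, manifest with input digests).

What the synthetic data does **not** emulate: peptide-to-protein
inference, batch-specific identification bias, instrument drift,
correlated protein abundances, and scale (hundreds rather than
thousands of proteins, thousands rather than tens of thousands of
network nodes).  Passing tests therefore demonstrate correctness of the
arithmetic and calibration of the statistics under the stated models,
not performance on real LC-MS/MS data.

## Numerical choices and degenerate inputs

Hypergeometric tails and χ² survival functions are computed in log
space by scipy; LR statistics are clipped at 0 against floating-point
cancellation; BH preserves input order and clips at 1; empirical p
never returns 0; zero-variance nulls report z = 0; all-zero batches,
empty null samples, constant vectors, infeasible annotation designs,
and sets mapping fewer than two genes into the network raise typed
errors naming the offending object.  Problem sizes in the test suite
and acceptance script (networks of 300–400 nodes, 1,000 calibration
trials at M = 200, M = 1000 for power, 5,000 null proteins, 20–100
replicates) were chosen to make Monte-Carlo error small relative to
each assertion's margin while keeping a full run in well under an hour
on one CPU.
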