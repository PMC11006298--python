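# Methods

## Model and procedure

The pipeline treats a curated list of differentially expressed genes
(DEGs) as noisy evidence about a coherent molecular programme and uses a
protein–protein interaction (PPI) network as the prior linking that
evidence together. It has four stages.

### 1. Signed seed construction

Each evidence row (gene, direction, significance) is scored
`s = sign(direction) · (−log10 p)`, UP positive and DOWN negative. The
orientation is a convention — the upstream literature fixes only "log10
transform plus a sign" — chosen so that stronger significance yields a
larger magnitude and the two diffusion tails cleanly separate up- and
down-regulated neighbourhoods.

Star tiers are mapped to their boundary p-values (`*` → 0.05, `**` → 0.01,
`***` → 0.001). Boundaries, not midpoints, because evidence tables report
only the bound: the boundary is the most conservative value consistent
with the row, and it is reproducible without further assumptions. A cell
listing several tiers (multi-study rows) resolves to the weakest listed
tier for the same reason. `N/A` significance resolves to the weakest tier
(`*`) with a logged warning; `na_policy="drop"` removes such rows instead.

Genes with multiple rows combine by **signed sum** by default:
independent corroborating studies reinforce, contradicting ones
attenuate. `max_abs` (largest magnitude wins, exact ties fall back to the
sum) is available as a sensitivity option; which aggregation the original
analyses used is generally unstated, so both are exposed rather than one
asserted.

### 2. Connectivity significance

The statistic is the number of network edges internal to the mapped seed
set. The null is Monte-Carlo over random k-node sets; `uniform` matches
the plain "randomly picked proteins" null, while `degree_matched`
(stratified by degree decile of the observed seeds) guards against the
seeds simply being network hubs. The empirical p-value uses the add-one
permutation convention `(1 + #{null ≥ obs}) / (1 + n_samples)`, so it is
never zero and is floored at `1/(n_samples+1)`.

Because genuinely interconnected seed sets exceed every feasible
Monte-Carlo sample, a parametric tail is reported alongside: the Poisson
upper tail `P(X ≥ obs)` with rate equal to the null mean. Poisson rather
than normal because the statistic is a small count; the analytic
expectation `C(k,2) · density` is exactly the uniform-null mean (each
pair of seed slots covers any fixed node pair with equal probability), a
fact the tests check against simulation.

### 3. Regularised Laplacian diffusion

With `L = D − A` (binary adjacency by default; the `weighted` flag uses
the edge confidences), the kernel is `K = (I + σL)⁻¹`. Properties relied
on downstream, all asserted in tests: K is symmetric positive definite;
`K·1 = 1`, hence diffusion conserves the seed sum; σ → 0 gives back the
seeds and σ → ∞ averages them per connected component; components do not
leak into each other. Default σ = 1 — the conventional default for this
kernel family; nothing in the analysed setting pins the parameter, and
results at the selection stage depend on score ranks, which vary slowly
in σ.

Numerics: the kernel is never inverted explicitly. For graphs up to
~2,000 nodes a dense solve of `(I + σL)K = I` is used where the full
matrix is requested; the pipeline itself always goes through a sparse LU
factorisation (`LaplacianKernel`) applied to the seed vector, so large
graphs cost one sparse solve. Raw scores `f = Ks` are used unnormalised,
matching a "most positive / most negative" ranking; z-scoring or
permutation normalisation is deliberately out of scope.

Selection takes `m = round(q·|V|)` nodes per tail over the whole network
node set (q default 0.01). Boundary ties break lexicographically by
identifier, so selections are deterministic; with all-equal scores this
degenerates to the alphabetically first m nodes, which is documented
rather than hidden.

### 4. Hypergeometric enrichment

Each tail selection is tested per pathway with the hypergeometric upper
tail `P(X ≥ k)` (over-representation only), with pathway size K counted
inside the universe. The universe is all network nodes — the diffusion
ranked all of them — with restriction to annotated nodes available as an
option. The pass/fail flag mirrors the dot-plot filters: overlap `k ≥ 3`
and raw `p < 0.05`. Benjamini–Hochberg q-values are computed across all
pathways with K ≥ 1 (zero-overlap pathways enter the correction at p = 1)
and reported, but do not enter the flag, keeping the filter semantics of
the original figure.

The tail itself is evaluated via scipy's log-space hypergeometric
survival function; tests pin it against an exact big-rational summation
oracle (≤ 1e−12 relative error on random large cases) and exhaustive
subset enumeration for all universes up to 12.

## Synthetic benchmark

The generator emulates the structure of the real inputs at desk scale:

- **Network**: preferential attachment (default N = 2,000, 3 edges per
  node) for a heavy-tailed, PPI-like degree distribution; Erdős–Rényi
  available where a homogeneous null is wanted. Node count 2,000 keeps a
  full-pipeline replicate around a second on one CPU.
- **Planted module**: 45 nodes (the size of the mapped seed set the
  pipeline is designed around) densified by adding each absent internal
  edge with probability p_in = 0.25, creating the excess-connectivity
  signal the test detects.
- **DEG table**: module genes get p ~ Beta(0.05, 1) and direction UP with
  probability 0.9 (coherent but not perfect signal); 100 background genes
  get uniform p and fair-coin direction. Rows with p ≥ 0.05 are dropped,
  mirroring curated tables that list only significant findings — so some
  background genes appear as plausible-looking false seeds. Note the
  emitted signal rows are conditioned on p < 0.05: with Beta(0.05, 1),
  P(p < 0.001 | p < 0.05) ≈ 0.82, which is the tier-*** fraction tests
  assert.
- **Pathways**: 5 true sets (size 20–80, half their members drawn from
  the module) and 45 decoys drawn from the background.

All generators are bit-reproducible given their seed; bundles carry a
`truth.json` sufficient to score recovery without touching generator
internals.

What passing the synthetic benchmark does **not** show: the generator
makes no attempt to mimic STRING's confidence-score distribution,
Reactome's hierarchical redundancy, correlated multi-study evidence, or
literature-bias in which genes get tested. Recovery rates here bound
sanity, not real-data performance.

## Determinism

Every stochastic step takes an explicit integer seed; bundle generation
derives per-stage child seeds via `SeedSequence.spawn`. All serialised
outputs are sorted with fixed float formatting, so identical
configuration and seed give byte-identical files.

## Known limitations

- The alias map is exact-match, single-species; no ortholog or synonym
  resolution.
- The connectivity null offers uniform and degree-decile-matched draws,
  not configuration-model rewiring.
- Only the regularised Laplacian kernel is implemented (no heat kernel or
  personalised PageRank), and only raw diffusion scores are ranked.
- Enrichment is over-representation only; no rank-based (GSEA-style)
  statistics.
- Reproducing published full-scale numbers requires the external STRING
  v11 network and a Reactome GMT, which are not shipped; at that scale
  the exact expected-edge count and selection size depend on the
  database release and on choices (universe, score type) those analyses
  leave unstated.
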