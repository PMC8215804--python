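# Methods

## Scope and model

`netpharm` integrates three evidence layers around a set of *seed* genes
(functionally validated cancer drivers, e.g. human orthologs of common
insertion site genes from an insertional-mutagenesis screen):

1. a protein–protein interaction (PPI) layer, restricted to interactions
   that involve a seed ("base network");
2. a drug layer, grafting drug→target edges for drugs whose targets are in
   the network;
3. a transcriptomic layer, annotating each protein node with per-subgroup
   differential expression versus a normal reference.

Discovery then asks which *druggable* proteins are over-expressed in every
tumour subgroup and how many distinct seeds they touch. A protein adjacent
to ≥ 2 distinct seeds is a **bridging node**. This is a deliberate,
topology-only operationalization: it needs no betweenness threshold, is
exactly checkable against brute-force seed-adjacency counting, and matches
the canonical examples (a tubulin hub touching CDKN2A/MAP3K1/TJP1; CDK6
touching CDKN2A/ZEB1). A betweenness-centrality definition was considered
and rejected as under-determined (no published cutoff to anchor it).

## Differential expression

Two-group empirical-Bayes moderated t per probe. With pooled variance
`s2_g` on `d_g = n1 + n2 - 2` df:

```
s2~_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)
t~_g  = (mean_case - mean_ref) / (s2~_g * (1/n1 + 1/n2))^(1/2)
p_g   = 2 * P(T_{d0+d_g} > |t~_g|)
```

`(d0, s0^2)` are fitted by matching the empirical mean and variance of
`log s2_g` to the scaled-F model, with the trigamma inverse solved by
damped Newton iteration (relative tolerance 1e-10). If the spread of log
variances does not exceed pure sampling noise, `d0 = inf` and all probes
share `s0^2`. The implementation is validated three ways: the `d0 = 0`
limit equals `scipy.stats.ttest_ind` (equal-variance) to 1e-10; the
shrinkage identity is checked directly; and the full fit agrees with
Bioconductor limma (`lmFit` + `eBayes`) to ~1e-6 relative on a shared
matrix.

Degenerate probes: zero moderated variance with zero mean difference gives
`t = 0, p = 1`; with nonzero difference the statistic is flagged infinite
and `p` is set to the smallest positive float (keeping `p` in (0, 1]), with
a warning.

**FDR.** Benjamini–Hochberg step-up, implemented from the definition and
cross-checked against an O(n²) enumeration oracle and statsmodels.

**Gene-level calls.** A gene is called over-expressed if *any* of its
probes has `q < alpha` (default 0.05) and `lfc > min_lfc` (default 0: no
fold-change filter beyond direction, since significance at FDR 0.05 is the
stated criterion). Every gene also carries a representative "best" probe —
smallest q, ties by largest |lfc| then probe id — whose statistics become
the network node attributes. Note the edge case this implies: a gene can be
called via one probe while its best-q probe is down-regulated; the stored
attributes describe the best probe, and `select_upregulated` with an
explicit `alpha` re-thresholds those best-probe attributes (which is what
makes selection monotone in alpha), while `alpha=None` uses the stored
any-probe flag.

**Normalization order.** Rows (probes) are z-scored across the cohort
first, then sample columns are centred and scaled, before model fitting;
both steps are configurable. The t statistic is invariant to the per-row
affine transform; column standardization makes per-array distributions
comparable. A consequence worth knowing: row z-scoring compresses the
spread of residual variances, so the moment fit returns a large `d0` and
shrinks strongly toward `s0^2`. That slightly deflates the statistic for
genes whose within-group variance is genuinely low (e.g. strongly shifted
genes) — visible in the recovery experiments as occasional near-threshold
misses — but it is the standard consequence of standardize-then-moderate
and is applied uniformly.

**Reference pooling.** Each tumour subgroup is contrasted against all
normal groups pooled (foetal + adult cerebellum) by default; explicit
`ComparisonSpec`s override this. Samples from groups outside the contrast
(e.g. a WNT-like group) are simply never used in any fit.

## Network construction

Node ids are namespaced (`P:SYMBOL`, `D:drug_id`) so drug names cannot
collide with gene symbols. Symbols are upper-cased before matching. The
base network keeps exactly the PPI edges with ≥ 1 seed endpoint — a strict
reading of "interactions involving the seeds"; `include_neighbor_edges=True`
additionally keeps edges between two retained non-seed proteins. Seeds with
no retrieved interaction stay as isolated nodes (they are real anchors and
belong in the reported component structure). Self-loops and duplicate
unordered pairs are removed; duplicate collapse is logged at debug level.
`attach_drugs` is idempotent; drug–target edges are always drug–protein
(bipartite typing is asserted in tests after every operation).

## Sub-network extraction

`expand_one_step` takes the selected over-expressed protein nodes and adds
all direct neighbours — neighbouring proteins and any drugs targeting the
inputs — then induces the subgraph (edges among two neighbours are kept,
matching how such networks are drawn; `induced=False` gives star-only
semantics). Per-node provenance (`overexpressed` / `neighbor` / `drug`) is
recorded and asserted as an invariant. The *refined common* network applies
the same operator to the genes called in every subgroup; its largest
connected component is the "central component". Components are ordered by
size, then lexicographic smallest member, for stable diffs.

## Synthetic data generator

The generator emulates the real inputs at desk scale with planted,
recoverable structure. Defaults are the study conditions used by the
recovery experiments and were fixed up front:

| parameter | default | rationale |
|---|---|---|
| groups | SHH/Gp3/Gp4 + normal_fetal/normal_adult, 12 samples each | three tumour subgroups vs pooled normal; 12/group is a realistic subgroup size at which moderation matters |
| effect_lfc | 1.5 log2 units | a strong but not trivial over-expression signal |
| noise_sd | 0.7 log2 units | typical array-scale residual noise |
| n_genes / n_seeds | 500 / 30 | keeps the full pipeline sub-second while leaving a large null background |
| mean_degree | 3.0 | sparse Erdős–Rényi background |
| n_drugs × targets_per_drug | 60 × 2 | ~20% of genes drugged, as a plausible druggable fraction |
| probes_per_gene_max | 3 | exercises the any-probe rule |
| planted common / specific / bridging | 20 / 10 per group / 8 | enough planted genes for stable sensitivity estimates |

Construction: gene symbols are synthetic (`GN00001` …); mouse symbols are
the title-cased human symbols, with a configurable fraction of one-to-many
rows made by letting two human genes share a mouse symbol. The PPI is
Erdős–Rényi at the configured mean degree with deterministic overlays:
every seed gets degree ≥ 1 and every planted bridging gene is wired to two
distinct seeds and given at least one drug. Expression is a per-probe
Gaussian baseline (mean 7, SD 1) plus i.i.d. N(0, noise_sd) noise, with
+effect_lfc added to all probes of a planted gene in that subgroup's
samples. Each artifact draws from its own RNG sub-stream of the root seed,
so changing one artifact's size never perturbs another.

The recorded truth derives from the *realized* artifacts:
`planted_common` is the intersection of the per-subgroup planted sets, and
`planted_bridging` is the subset of planted common genes that are drugged
and adjacent to ≥ 2 seeds in the emitted PPI (so chance wiring counts as
truth, and recovery metrics measure exactly what is in the data).

What the generator does *not* emulate — Affymetrix intensity distributions,
array normalization artefacts, correlated co-expression modules, scale-free
PPI degree distributions, ortholog ambiguity beyond symbol sharing — bounds
what passing recovery tests show: they demonstrate that the pipeline's
operators are correct and well calibrated under the stated noise model, not
that real-cohort sensitivity reaches the same values.

## Numerical and design choices

- Tie-breaks are fixed everywhere (best probe: q, then |lfc|, then probe
  id; reports: seed-partner count desc, then symbol; ranking: subgroups
  called, partners, degree, symbol) so reruns are byte-identical.
- BH q-values are clipped to [0, 1]; p-values to (0, 1].
- Zero-variance rows/columns are dropped with warnings, never fatal.
- GraphML/SIF/TSV writers sort nodes and edges; `read(write(G))` reproduces
  the graph exactly (NaN attributes compare equal to NaN).
- The manifest carries SHA-256 checksums of all inputs and per-stage
  counts; counts are revalidated against the emitted files in tests.
- Experiment sizes in the test suite (≈5000 probes for null calibration,
  20 simulated cohorts for recovery, 100 random graphs per oracle suite)
  were chosen to give stable estimates while keeping the whole suite fast.

## Known limitations

- The moderated t assumes equal group variances and independent Gaussian
  log-intensities; no multi-factor designs, batch correction or array
  preprocessing (e.g. RMA) are provided.
- Published network sizes from any specific cohort/database snapshot are
  not reproducible without those exact snapshots; the package reproduces
  operators and worked-example structure, not database-dependent counts.
- Bridging detection is purely topological; it does not score binding
  affinity, brain penetrance or efflux-transporter liability of the drugs.
- One-step expansion is fixed; k-step neighbourhoods are out of scope.
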