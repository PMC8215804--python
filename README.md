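# netpharm

Seed-anchored drug–target network analysis for tumour transcriptomics.

`netpharm` is for computational biologists who have a set of functionally
validated candidate cancer genes — for example human orthologs of common
insertion site (CIS) genes from a Sleeping Beauty insertional-mutagenesis
screen — and want to turn them into prioritized, already-druggable
therapeutic targets for a tumour cohort. The motivating application is
medulloblastoma (MB): finding drugs whose targets are over-expressed in all
non-WNT subgroups (SHH, Group 3, Group 4) relative to normal foetal and
adult cerebellum.

The pipeline:

1. **Seed mapping** — mouse CIS symbols → human orthologs (one-to-many rows
   kept).
2. **Base network** — all protein–protein interactions involving a seed.
3. **Drug grafting** — drug→target edges added for drugs hitting network
   proteins, giving a typed protein/drug graph.
4. **Differential expression** — per-subgroup empirical-Bayes moderated
   t-tests versus pooled normal reference, Benjamini–Hochberg FDR at
   q < 0.05, any-probe gene-level over-expression calls.
5. **Discovery** — per-subgroup and common (all-subgroup) sub-networks
   (over-expressed nodes plus their direct neighbours and targeting drugs),
   druggable-target reports with seed partners, and **bridging nodes**:
   druggable over-expressed proteins adjacent to ≥ 2 distinct seeds.

## The statistics at the core

For probe *g* with pooled two-group variance *s²_g* on *d_g = n₁+n₂−2*
degrees of freedom, the moderated t shrinks the variance toward an
empirical prior (*d₀*, *s₀²*) fitted by method of moments on log *s²_g*:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t̃_g  = (x̄₁ − x̄₂) / ( s̃_g · √(1/n₁ + 1/n₂) ),   t̃_g ~ t(d₀ + d_g) under H₀

With *d₀ = 0* this is exactly the classic pooled two-sample t; the test
suite verifies both that limit (to 1e−10) and numerical agreement with the
Bioconductor limma implementation. FDR control is Benjamini–Hochberg
step-up, `q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j`.

## Worked example

A fully enumerated MB example ships in `netpharm.datasets`: six seed (CIS)
proteins (CDKN2A, ZEB1, MAP3K1, TJP1, PTN, PPP2R5E), ten over-expressed
druggable interactors and thirteen PPI edges.

```python
from netpharm import datasets
from netpharm.netbuild import connected_components

res = datasets.analysis()
comps = connected_components(res["base"])
print(f"base network: {res['base'].number_of_nodes()} proteins, "
      f"{res['base'].number_of_edges()} PPI edges, {len(comps)} components "
      f"(largest: {len(comps[0])})")
for r in res["druggable"]:
    print(f"  {r.protein:<7} partners={','.join(r.seed_partners)}")
print("bridging:", ", ".join(b.protein for b in res["bridging"]))
```

prints

```
base network: 16 proteins, 13 PPI edges, 3 components (largest: 11)
  TUBB    partners=CDKN2A,MAP3K1,TJP1
  CDK6    partners=CDKN2A,ZEB1
  AURKA   partners=CDKN2A
  CAD     partners=MAP3K1
  CDK4    partners=CDKN2A
  CHEK2   partners=PPP2R5E
  P4HB    partners=PTN
  PTPRS   partners=PTN
  SLC1A5  partners=MAP3K1
  SNRPA   partners=CDKN2A
bridging: TUBB, CDK6
```

TUBB (three seed partners, targeted by the microtubule-stabilizing agent
ixabepilone) and CDK6 (two partners) are the bridging nodes — druggable
proteins that connect otherwise separate seed neighbourhoods and are
therefore the top repurposing candidates.

## Command line

```sh
netpharm simulate --config gen.yaml --seed 7 --out inputs/   # synthetic cohort
netpharm de --matrix M.tsv --annot A.tsv --probes P.tsv \
            --case Gp3 --ref normal_fetal,normal_adult --alpha 0.05 --out de/
netpharm build-net --seeds cis.txt --orthologs o.tsv --ppi ppi.tsv \
                   --drugs drugs.tsv --out net.graphml
netpharm discover --net net.graphml --common common.txt --out report/
netpharm run --config run.yaml                               # full pipeline
```

All inputs are plain TSV; networks are written as Cytoscape-importable SIF
and GraphML plus a node-attribute table, and every run emits a JSON
manifest (input checksums, parameters, per-stage counts). Runs are
deterministic: the same config yields byte-identical reports.

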