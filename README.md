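# refstab

Reference-gene expression-stability analysis for RT-qPCR Cq data.

Accurate qPCR quantification requires normalizing each target gene
against reference genes whose own expression is stable across the
samples and conditions under study — and "commonly used" references
(ACTB, GAPDH, …) are often not stable at all. Given a complete Cq
(quantification-cycle) table of candidate reference genes with a group
label per sample, `refstab` ranks the candidates with the four
established stability statistics, aggregates them into a consensus
ranking, selects how many genes the normalization factor needs, and
validates chosen panels on target genes:

- **geNorm** — M_j = mean over partners k of SD(log₂ q_j/q_k), stepwise
  exclusion, and pairwise variation V(n, n+1) with the 0.15 threshold
  for the optimal gene count;
- **model-based (NormFinder-style)** — variance decomposition of log₂
  expression into intragroup noise σ̂²_ig and shrunken intergroup
  deviation d̃_ig, stability ρ_i = mean_g [|d̃_ig| + √(var d̃_ig)];
- **BestKeeper** — mean-absolute-deviation SD(±CP) and CV on raw Cq,
  x-fold extremes, and Pearson correlation of each gene with the
  per-sample geometric-mean index;
- **comparative ΔCt** — mean pairwise SD of Cq differences;
- **consensus** — geometric mean of the four methods' ranks.

The package ships a published 30-sample × 10-gene bovine PBMC dataset
(cattle populations adapted to cold-arid high-altitude hypoxia vs
hot-arid normoxia) as a worked example and reproduction target, and a
synthetic-data generator with known variance structure so every method
is testable by parameter recovery.

## Worked example

```python
from refstab import ReferenceGeneStability, load_pbmc_cq

model = ReferenceGeneStability(load_pbmc_cq())
res = model.fit()          # genorm, normfinder, bestkeeper, deltact
print(res.summary())
```

```
Reference-gene expression stability
====================================================================
samples: 30   genes: 10   groups: {'cold_arid': 15, 'hot_arid': 15}

        genorm  normfinder  bestkeeper  deltact  geo_rank
gene
RPS9     0.465       0.360       0.580    0.914     2.000
RPS15    0.465       0.359       0.551    0.925     2.060
GAPDH    0.540       0.300       0.521    0.977     2.378
RPL4     0.527       0.236       0.620    0.954     2.590
HMBS     0.561       0.426       0.549    1.008     3.976
B2M      0.655       0.567       0.629    1.147     6.735
EEF1A1   0.591       0.700       0.768    1.095     6.901
UXT      0.825       0.444       1.035    1.471     7.445
ACTB     0.995       0.619       1.293    1.632     8.739
HPRT1    1.228       1.826       2.077    2.161    10.000

pairwise variation: V2/3=0.169  V3/4=0.116  V4/5=0.101  V5/6=0.092  V6/7=0.103  V7/8=0.158  V8/9=0.165  V9/10=0.204
optimal number of reference genes: 3 (threshold 0.15)
most stable pair (geNorm): RPS9/RPS15 (M = 0.465)
consensus ranking: RPS9 > RPS15 > GAPDH > RPL4 > HMBS > B2M > EEF1A1 > UXT > ACTB > HPRT1
```

Reading the output: the geNorm column is the average-M stability curve
(lower = more stable; RPS9/RPS15 share the terminal value 0.465 and
HPRT1, excluded first, sits at the all-genes average 1.228); V3/4 =
0.116 is the first pairwise variation below 0.15, so three reference
genes suffice; BestKeeper's SD column flags UXT, ACTB and HPRT1 (> 1
cycle) as unacceptable; and the consensus picks `RPS9, RPS15, GAPDH` —
`res.recommended_panel()` — as the panel, with the conventional
defaults ACTB and HPRT1 ranked worst. Per-environment analyses
(`model.fit(subset_group="cold_arid")`) give the within-condition
rankings, and `refstab.validate.panel_contrast` compares best- vs
worst-panel normalization of target genes, flagging direction
reversals of group differences.

The same pipeline is scriptable:

```sh
refstab analyze --input my_cq.csv --outdir reports    # or --input fixture
refstab simulate --seed 7 --out synthetic.csv
refstab reproduce
```

Input is a comma- or tab-delimited table, samples as rows, first column
sample ids, optional `group` column, gene columns of Cq values (a
`genes-as-rows` orientation flag exists in the library API).

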