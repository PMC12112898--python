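# refstab

Reference-gene identification and validation for RT-qPCR, with a
transcriptome-count screening stage and a synthetic benchmark generator.

Relative RT-qPCR quantification reports a target gene's expression as a
ratio to one or more *reference* (housekeeping) genes, assumed stable
across all samples. Classically used references such as actin (*act1*) or
*sar1* in filamentous fungi are often condition-regulated, which silently
biases every normalized fold change. `refstab` is for molecular biologists
and bioinformaticians who need to (1) shortlist candidate reference genes
from public transcriptome count matrices, (2) rank candidates by
expression stability from their own qPCR Ct values, and (3) quantify
targets against the chosen references — with every step testable against
simulated data with known ground truth.

## What it computes

* **CV screen** — counts are normalized with median-of-ratios size factors
  (*s_j* = median_i K_ij / geomean(K_i·) over genes with no zero count);
  candidates are the genes with the lowest coefficient of variation
  CV = σ/μ among those with mean normalized count ≥ 100. Two annotations'
  matrices can be joined through a strict 1:1 ortholog map.
* **Stability ranking** — four classical algorithms on the aggregated
  gene × sample Ct matrix:
  geNorm (M_j = mean_{k≠j} SD_s log2 Q_j/Q_k, stepwise exclusion),
  NormFinder (model-based residual SD of log2 quantities, grouped or
  ungrouped), BestKeeper (SD/CV of Ct and correlation with the
  geometric-mean index) and the comparative ΔCt method
  (mean_{k≠j} SD_s(Ct_j − Ct_k)); the consensus is the geometric mean of
  the four ranks, Q(g,s) = E_g^(minCt − Ct) with efficiency E ∈ (1, 2].
* **Relative expression** — multi-reference, efficiency-aware ΔΔCt:
  log2 FC = log2(E_t^ΔCt_t / geomean_r E_r^ΔCt_r) against a calibrator
  condition, with replicate-level SDs. At E = 2 this is the classic −ΔΔCt.
* **Synthetic data** — seeded generators for replicate-resolved Ct tables
  (factorial strain × condition × timepoint design, per-sample loading
  shifts) and negative-binomial count matrices, each returning the
  injected ground truth.

See `docs/methods.md` for formulas, defaults and assumptions.

## Worked example

Simulate the default validation study — 7 genes (five stable candidates
plus regulated *act1*/*sar1* analogues) under 2 strains × 7 conditions ×
2 timepoints × 2 biological × 2 technical replicates — then rank:

```sh
refstab simulate --seed 1 --out-dir demo
refstab stability demo/ct.csv --subset-by strain \
    --out-json demo/stability.json --out-tsv demo/stability.tsv
# wrote demo/stability.json and demo/stability.tsv; most stable gene: tpc1
```

The ranked table (columns abridged):

```text
gene  genorm_m  normfinder_rho  bestkeeper_sd  deltact_sd  composite_geomean  final_rank
tpc1    0.5380          0.1960         0.4638      0.5380             1.1067         1.0
bzp1    0.5413          0.2206         0.4787      0.5413             2.0598         2.0
ubi1    0.5658          0.2918         0.4691      0.5658             3.0801         3.0
sas3    0.5689          0.2362         0.5162      0.5689             3.9360         4.0
cue1    0.5804          0.2860         0.5027      0.5804             4.4721         5.0
act1    0.9753          0.8182         0.8685      0.9753             6.0000         6.0
sar1    1.3092          1.2458         1.2971      1.3092             7.0000         7.0
```

The two regulated analogues (injected condition-effect SDs of 0.8 and 1.2
cycles vs ≤ 0.15 for the candidates) land in the last two positions of the
consensus, with the more strongly regulated *sar1* analogue last; lower
geNorm M / NormFinder ρ / SD values mean more stable expression. (At the
default E = 2, geNorm's initial M and the ΔCt stability coincide — both
are mean pairwise SDs of Ct differences.)

Quantifying the *act1* analogue against the two best references:

```sh
refstab express demo/ct.csv --target act1 --refs bzp1,tpc1 \
    --calibrator QM6a:glucose:early --out demo/act1.tsv
head -4 demo/act1.tsv
```

```text
strain  condition  timepoint  log2fc              sd                   n_replicates
QM6a    cellulose  early      1.2273621664981773  0.1508375130723413   4
QM6a    cellulose  late       1.0795740546485568  0.10803091517218688  4
QM6a    glucose    early      0.0                 0.17906527526090954  4
```

The calibrator cell is 0 by construction; nonzero log2 fold changes of a
would-be reference gene are exactly the regulation that disqualifies it.

The same analyses are available as library estimators:

```python
import refstab as rs
table, truth = rs.generate_ct_dataset(rs.CtDesign(), rs.default_gene_panel(), seed=1)
ranker = rs.StabilityRanker(subset_by="strain").fit(table)
ranker.scores_.ranked()          # the table above
ranker.pairwise_variation_      # geNorm V(n, n+1) series
```

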