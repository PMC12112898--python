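# Methods

## Problem setting

Relative RT-qPCR quantification divides a target gene's signal by that of
one or more reference (housekeeping) genes to cancel sample-to-sample
differences in RNA input and reverse-transcription efficiency. A reference
gene that is itself regulated biases every normalized result, so candidate
references must be screened and validated. `refstab` implements that
workflow end to end: a transcriptome-wide coefficient-of-variation screen,
a four-algorithm expression-stability ranking with a consensus, and
calibrator-relative fold-change computation — plus a seeded synthetic-data
generator so the whole chain can be validated against known ground truth.

## Count screening

Raw count matrices are normalized with median-of-ratios size factors: for
sample *j*, *s_j* = median over reference genes *i* of
*K_ij* / geomean_j(*K_i·*), where the reference set is every gene with a
nonzero count in all samples (strict zero-exclusion, no pseudocounts; a
matrix without any such gene raises instead of silently falling back).
Per gene we report the mean normalized count and the coefficient of
variation CV = SD/mean (linear count scale, n−1 SD); candidates are the
`top_k` lowest-CV genes with mean ≥ `min_mean`.

Defaults: `min_mean = 100` normalized counts and `top_k = 25`. The floor
encodes "medium-to-high expression" on typical bulk libraries; 25 is a
practical shortlist size for follow-up qPCR validation. Both are exposed
as estimator parameters. Matrices from two genome annotations can be
joined beforehand through an ortholog map reduced to strict 1:1 pairs
(every pair touching a duplicated gene is removed — conservative and
reproducible rather than arbitrated).

## Stability algorithms

All four methods run on a complete gene × sample Ct matrix obtained by
arithmetic-mean aggregation of technical replicates (biological replicates
stay separate samples). Genes with any missing Ct after aggregation are
excluded (complete-case; no imputation) because all four methods assume
complete matrices. Relative quantities are Q(g,s) = E_g^(minCt_g − Ct(g,s))
with per-gene amplification efficiency E ∈ (1, 2], default 2. With E = 2,
log2 Q is just minCt − Ct, so geNorm/NormFinder arithmetic reduces to the
Ct scale — matching how Ct-only consensus tools treat their input. All SDs
use the n−1 denominator.

* **geNorm.** V_jk = SD_s(log2 Q_j/Q_k); M_j = mean_{k≠j} V_jk. The
  highest-M gene is removed and M recomputed until two genes remain; those
  two are inseparable by construction and share rank 1.5. Ties during
  elimination remove the lexicographically last gene label
  (deterministic). The pairwise-variation series V(n, n+1) compares
  normalization factors (per-sample geometric means of the top n vs n+1
  genes) and guides how many references to combine. Note that the initial
  M values coincide with the comparative ΔCt stabilities when all E = 2 —
  both are mean pairwise SDs of Ct differences — but the stepwise ranking
  and the ΔCt ranking can still differ from the third gene onward.
* **NormFinder.** On y = log2 Q, residuals of the additive gene + sample
  model are r = y − rowmean − colmean + grandmean. With gene-specific
  variances, E[Σ_s r²/(S−1)] = σ_g²(1 − 2/G) + Σ_h σ_h²/G², so the
  unbiased estimator is σ̂_g² = G/(G−2)·(d_g − Σ_h d_h/(G(G−1))) with
  d_g = Σ_s r²/(S−1), clipped at zero; ungrouped stability is ρ_g = σ̂_g.
  With sample groups, the same estimator runs within each group; the
  gene × group mean matrix is double-centered to give intergroup
  differences d_gk, which are shrunk by γ̂²/(γ̂² + σ̂²_gk/n_k) where
  γ̂² = Σ d²/((G−1)(K−1)) − mean(σ̂²/n) (floored at 0), and
  ρ_g = mean_k(|d̃_gk| + sqrt(σ̂²_gk/n_k)). A grouping without at least two
  groups of two samples falls back to the ungrouped analysis with a
  warning.
* **BestKeeper.** Descriptive on raw Ct: per-gene SD and CV% plus the
  Pearson correlation with the per-sample geometric-mean index. The
  consensus ranking key is the SD (ascending); r and CV are reported for
  inspection, and genes with SD > 1 cycle are flagged inconsistent per the
  tool's conventional guidance. A zero-variance gene keeps SD = 0 but has
  undefined r (NaN).
* **Comparative ΔCt.** Stability of gene g = mean over all other genes k
  of SD_s(Ct_g − Ct_k).

**Consensus.** Each method contributes a rank vector (1 = most stable;
fractional average ranks on ties; geNorm contributes its stepwise-exclusion
ranking). The composite is the geometric mean of the four ranks and the
final ranking is the fractional ranking of the composite. Subset analyses
(per strain, per timepoint, or per derived early/late stage — the first
harvest of each strain × condition is "early") rerun the full four-method
consensus independently within each subset; a subset violating a method's
minimum size is skipped with a warning rather than failing the run.

## Relative expression

Per replicate combination (biological × technical) with a Ct for the target
and every reference, the log2 relative quantity is
y = −Ct_t·log2 E_t + mean_r(Ct_r·log2 E_r) — the multi-reference
normalization factor is the geometric mean of the references' quantities,
i.e. an arithmetic mean on the Ct scale. Fold changes are y minus the mean
y of the calibrator cell's replicates; per condition cell we report the
mean and the n−1 SD over replicate combinations (a cell with a single
usable combination reports SD 0.0 by convention). With all E = 2 this is
exactly the classic −ΔΔCt; with measured efficiencies it equals
log2 of the Pfaffl ratio E_t^ΔCt_t / E_r^ΔCt_r (exposed directly as
`pfaffl_ratio`). Replicates missing any required gene are excluded with a
warning; a calibrator cell with no usable replicate is an error.
Computing per replicate first and aggregating afterwards (rather than
averaging Ct first) propagates replicate scatter into the reported SD.

## Synthetic data

The Ct generator draws
Ct(g, cell, bio, tech) = base_ct(g) + condition_effect(g, cell) +
bio_noise + tech_noise + loading_shift(sample), all noise Normal on the Ct
scale (Ct is a log2-abundance, so this is a log-normal abundance model).
`condition_effect` is either N(0, cond_sd²) per strain × condition ×
timepoint cell or user-fixed offsets (for deterministic regulation
patterns); the loading shift is shared by all genes of a biological sample
and models the RNA-input/RT nuisance that reference-gene normalization
removes. The truth object records every injected and realized parameter
and the expected stability order, which sorts genes by
sqrt(cond_sd² + bio_sd² + tech_sd²/tech_reps) — the per-sample SD that
survives technical averaging.

Default study design: 2 strains × 7 conditions × 2 timepoints ×
2 biological × 2 technical replicates (112 measurements per gene). The
default 7-gene panel has five stable candidates (cond_sd 0.05–0.15 cycles)
and two regulated analogues of the classically used actin and sar1 genes
(cond_sd 0.8 and 1.2; the sar1 analogue is the more variable), all with
bio_sd 0.15, tech_sd 0.10, and loading_sd 0.5 cycles — replicate scatter
of a tenth to a few tenths of a cycle and loading spreads of about half a
cycle are typical of careful qPCR practice, and a ≥ 0.8-cycle condition
effect corresponds to ~1.7-fold regulation, enough to disqualify a
reference gene.

The count generator draws gene counts NB(mean = μ_condition × library
factor, var = μ + α μ²) with log-normal library factors (natural-log SD,
default 0.1) via the gamma–Poisson mixture, so α = 0 is exactly Poisson.
The default 2000-gene compendium panel has 25 designated stable genes
(condition-constant mean log-uniform in [500, 5000], α = 0.01) among
background genes with log-uniform base means in [10, 10⁴], per-condition
log-normal swings (σ = 0.5) and α ∈ [0.05, 0.2], over 14 conditions × 2
replicates — emulating the statistical shape of a heterogeneous
public-dataset compendium (many conditions, biological duplicates) without
modeling read-level artifacts.

What the generators deliberately omit: amplification-curve artifacts,
inter-run batch effects, primer-specific efficiency drift, count length/GC
bias and read-level noise. Passing recovery tests therefore demonstrates
the statistical machinery is correct under the stated generative model,
not that any particular real dataset satisfies that model.

## Numerical and design choices

* Ct validity range (0, 45]; technical-replicate spreads > 1.0 cycle are
  flagged, never dropped (flag-only QC heuristic; both configurable).
* Screen output order is CV ascending with ties broken by gene label;
  rank values themselves stay fractional. Stability rankings are invariant
  to input gene order.
* Reports serialise to JSON with sorted keys and shortest round-trip float
  reprs, so identical analyses give byte-identical files (the determinism
  contract of the CLI).
* Problem sizes used by the validation scripts — 200 replicates of the
  7-gene study design, 50 replicates of the 2000 × 28 count screen, 20
  replicates of the 28-cell fold-change contrast — give stable rates
  (binomial SE below ~2 percentage points) while keeping a full run in the
  tens of seconds.
* Known limitations: no missing-data imputation; BestKeeper's descriptors
  follow the SD-of-Ct convention of consensus tools rather than the
  original spreadsheet's MAD-based variant; efficiency correction assumes
  a single E per gene across runs; the grouped NormFinder shrinkage
  assumes roughly balanced groups.
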