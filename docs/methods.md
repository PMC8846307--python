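# Methods

## Problem and data model

RT-qPCR quantifies a target transcript against one or more *reference
genes* assumed stable across samples and conditions. Choosing that
panel is itself a statistical problem: given a complete Cq
(quantification-cycle) matrix of k candidate genes over n samples with
group labels (here: two cattle populations adapted to cold-arid
high-altitude hypoxia and hot-arid normoxia, 15 animals each, 10
candidates), rank the candidates by expression stability and decide
how many are needed.

One Cq cycle is one doubling at perfect efficiency, so Cq is a (negative)
log2 expression scale. Where an algorithm needs expression levels, Cq is
transformed to relative quantities q = E^(minCq − Cq) ∈ (0, 1], each gene
scaled to its most-expressed sample. The package default is E = 2 for
every assay because the transform the surveyed tools use is 2^−ΔCq
regardless of measured efficiencies; per-gene bases are accepted
everywhere (`efficiencies=` mappings) for users who want
efficiency-corrected quantities.

## The four stability statistics

**geNorm.** V_AB = SD(log2 q_A/q_B) over samples (n−1 denominator);
M_j = mean_k≠j V_jk. Stepwise exclusion removes the highest-M gene until
two remain. The value reported per step — and the per-gene "M value"
quoted in survey tables — is the *average* M of the genes still in play
at that step (the stability-curve ordinate), which is non-increasing and
ends at the tied terminal pair; each gene's own M at its exclusion step
is kept alongside (`own_m_of`). With E = 2, log ratios are raw Cq
differences up to a constant, so M is computable straight from Cq; the
implementation is tested against that identity at 1e-12. Pairwise
variation V(n, n+1) = SD(log2 NF_n/NF_{n+1}) over nested
normalization-factor sets (NF = per-sample geometric-mean RQ) with the
conventional 0.15 threshold; when no V falls below it, all k genes are
reported with a warning rather than an error, since the threshold is a
guideline.

**Comparative ΔCt.** score_j = mean_k≠j SD(Cq_j − Cq_k). Algebraically
identical to first-iteration geNorm M at E = 2; kept separate because the
consensus treats it as an independent vote.

**Model-based (NormFinder-style).** On x = log2 q, samples are centered
on their across-gene mean (removing loading), then per group g the
intragroup variance σ²_ig is estimated from the centered residual
variance v_ig with the bias correction
σ̂²_ig = max{0, (v_ig − Σv/(k(k−1))) · k/(k−2)} (re-derived from the
moment equations; centering mixes 1/k of every gene's noise into each
residual, hence undefined at k < 3). Intergroup deviations
d_ig = z̄_ig − mean_g z̄_ig are shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g), where
γ̂² = max{0, Σd²/((k−1)(G−1)) − Σ(σ̂²/n)/(kG)}, and the stability is
ρ_i = mean_g [ |d̃_ig| + √(σ̂²_ig/n_g · γ̂²/(γ̂² + σ̂²_ig/n_g)) ].
Ungrouped data reduce to ρ_i = σ̂_i. Negative variance estimates are
truncated at zero. Group centering is unweighted (groups are equal-sized
in the packaged data, so weighting is indistinguishable there). The
grouping is a caller-visible parameter: environments, breeds, any
sample→group map, or none.

**BestKeeper.** Runs on raw Cq. SD(±CP) is the mean absolute deviation
about the arithmetic mean (genes ≥ 1 cycle flagged unacceptable),
CV = 100·SD/mean, x-fold extremes anchor on the geometric mean
(min = −E^(geo−min), max = +E^(max−geo)), and the BestKeeper index is
the per-sample geometric mean Cq over all candidates, against which each
gene's Pearson r (and t-distribution p, reported with a 0.001 floor) is
computed. Both the MAD definition and the geometric anchoring were
validated cell-for-cell against the published descriptive table of the
packaged dataset; the arithmetic-anchored alternative reproduces none of
its x-fold entries.

**Consensus.** Each method's scores become integer ranks; the
comprehensive score is the geometric mean of the four ranks. geNorm's
tied terminal pair contributes rank 1 for *both* genes with competition
ranking (1, 1, 3, …) by default — this is the convention under which the
packaged dataset's published composite scores (1.41 = (1·1·4·1)^¼,
1.86 = (1·2·3·2)^¼, …, 10.00) are reproduced exactly, all ten of them;
consecutive tie-breaking is available. The model-based vote runs
ungrouped inside the consensus, matching how the upstream web tool
treats uploads, and BestKeeper votes by SD(±CP) (index-correlation
voting is an option).

## Known limitation: the model-based column of the original survey

The published NormFinder stability values for the packaged dataset
(e.g. 0.282 for the top gene under the two-environment grouping) are
not reproduced at value level by this implementation, under any
defensible configuration we tried: both log bases, environment vs
breed subgroupings vs ungrouped, raw vs bias-corrected intragroup
variances, with and without shrinkage, weighted and leave-one-out
centerings, and a free fit of γ². The closest configuration (natural
log, breed subgroups, unshrunken components) reaches rms deviation
0.014 on the combined column but degrades on the within-environment
columns, so it is not what produced the published numbers either; the
original Excel tool's internals are not recoverable offline. The
faithful computation above agrees with the published column on the
extremes (same most-stable and least-stable genes, same broad
ordering) and is what the package reports. Every other published
statistic of the dataset — all geNorm M and V values, the complete
BestKeeper table, all correlations, all ten consensus composites —
is reproduced at printed precision.

## Synthetic data generator

`generate_cq` draws Cq_igj = baseline_i + s_gj + shift_ig + ε_igj with
s ~ N(0, sample_factor_sd²) shared across genes within a sample and
ε ~ N(0, noise_sd_i²) — exactly the additive log-scale model the
stability methods assume, which is the point: every method becomes
testable by parameter recovery, and the loading term discriminates the
ratio-based methods (blind to it, by construction) from BestKeeper
(inflated by it). What it does *not* emulate: technical-replicate
structure, amplification inhibition, non-Gaussian outliers,
heteroscedasticity along the dilution range, or inter-gene noise
correlation beyond the shared loading factor — so passing recovery
tests show correctness of the estimators under their own model, not
robustness to real-world artefacts.

`paperlike_spec()` moment-fits all parameters from the packaged matrix
at call time (per-gene means as baselines; group-mean deviations as
shifts — including the ~4-cycle HPRT1 environment shift; per-sample
mean residuals for the loading SD, ~0.5 cycles; pooled within-group
residual SDs, loading removed, as noise SDs), so simulated matrices
mirror the study's structure without hard-coded constants.

## Numerical and design choices

- SDs use the n−1 denominator throughout; log base 2 everywhere except
  where a caller overrides it.
- geNorm exclusion ties break by removing the later gene in input
  column order; consensus ties by input gene order — both deterministic.
- Cq admissible range [5, 45] cycles, enforced at construction; missing
  values are rejected, never imputed (all scores are SD-type statistics
  that imputation biases). Matrices need ≥ 3 samples; single-gene
  matrices arise only as programmatic target views.
- Target-gene validation normalizes RQ_target/NF per sample. Because
  both target and panel quantities are anchored at their own per-gene
  minimum, the absolute level of the normalized series is
  scale-arbitrary; group contrasts (fold differences, SD, SE) are the
  meaningful output. A panel "reversal" is flagged only when the group
  difference exceeds 0.25 log2 units in *both* panels with opposite
  signs — sign jitter around a null difference is not a reversal.
- Report files round to 3 decimals; all comparisons in tests use
  unrounded values with explicit tolerances.
- Problem sizes in the stochastic tests (e.g. 100-sample recovery runs,
  200-replicate bias checks, 30–100 seed majorities) were chosen as the
  smallest sizes at which the asserted effects are stable, keeping the
  default suite fast.
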