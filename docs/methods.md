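# Methods

This note documents the models, estimators and numerical choices behind
`pmdecon`, and what its synthetic data does and does not emulate.

## Data model

All analyses operate on beta values — the methylation fraction at a CpG,
methylated / (methylated + unmethylated) signal, in [0, 1] — at the level of
a probes × samples matrix with a sample sheet (cell type, trimester, donor,
sex, optional normalized X/Y/autosomal intensity summaries) and a per-probe
annotation (genomic position, CpG-island and gene context, enhancer/PMD
flags, imprint category, repeat class, SNP-probe flag). Probe positions are
1-based; BED region files are 0-based half-open and converted exactly once
on read. Missing betas are propagated and excluded pairwise per operation;
nothing is imputed.

## Synthetic data generator

The generator emulates a cell-sorted placental EPIC experiment: six cell
populations (TB, HB, EC, SC, eSTB, nRBC) with replicate samples in two
gestational windows, plus bulk chorionic-villi (CV) mixtures of those
populations (term: eSTB-dominant; first trimester: SC-dominant, following
the composition a term/first-trimester placenta presents).

- **Baseline probes.** Per-probe means are bimodal (modes near β = 0.1 and
  0.85), the canonical shape of array methylomes.
- **Planted cell-specific DMCs.** For each cell type, disjoint probe sets
  are shifted ±0.30 (default) in that cell type only; hypo-DMC baselines are
  drawn from the methylated mode and hyper-DMC baselines from the
  unmethylated mode so clipping to [0.01, 0.99] never erodes the planted
  effect.
- **Gestational shifts.** Per cell type, a probe set gains +0.10 at term.
- **PMD blocks.** Contiguous probe runs where TB/eSTB sit at U[0.3, 0.6),
  EC/SC at U[0.55, 0.75), and HB/nRBC at U[0.8, 0.95) — intermediate
  methylation in trophoblast, somatic-like hypermethylation in Hofbauer
  cells.
- **Imprinted probes.** Placental-specific imprints: mean 0.5 in
  TB/eSTB/EC/SC, 0.05 in HB/nRBC; non-placental-specific imprints: 0.5
  everywhere.
- **Repeat probes.** Alu/LINE1 probes drawn from the methylated mode, with
  HB shifted +0.08 above the common level.
- **SNP probes.** 59 trimodal probes at cluster centers {0.05, 0.5, 0.95}
  indexed by per-donor genotypes drawn at allele frequency 0.5 under
  Hardy–Weinberg. All samples of a donor share its genotype, and villi
  inherit it (mixing weights sum to one).
- **Replicate noise.** A replicate at mean μ is Beta(μκ, (1−μ)κ); κ = 200
  (sd ≈ 0.035 at β = 0.5, ≈ 0.015 near the modes) reproduces visually tight
  within-cell-type replicates. The paper-scale data give no direct
  within-cell-type variance estimate, so κ is surfaced in the config;
  κ = ∞ disables noise (replicates equal their means), the limit used by
  exactness tests.
- **Intensity summaries.** Males: y_norm ≈ N(1.0, 0.02), x_norm ≈ 0.55;
  females: y_norm ≈ N(0.10, 0.01) (a background floor, as real Y probes
  show), x_norm ≈ 1.0.
- **Maternal contamination.** β_obs = (1−c)·β_sample + c·β_maternal applied
  probe-wise, with y/x_norm mixed identically. The maternal profile is
  somatic-like (stromal profile with fully methylated PMDs) and — key to
  realistic SNP behaviour — shares one allele per SNP with her own fetus,
  so mother–child pairs are never opposite homozygotes. Mixing is affine,
  so sequential admixture composes exactly.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry bias, batch/chip effects, detection failures, cross-hybridizing
probes, genomic autocorrelation beyond the planted PMD blocks, and
biological heterogeneity within a sorted population. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every artefact of real arrays.

## Contamination QC

1. **Sex inference** partitions normalized Y intensity with a deterministic
   1-D 2-means (initialized at the extremes). Ambiguity — the signature of
   a male diluted with female DNA — is judged against robust cluster
   centers (medians) with a MAD-based spread floored at 5% of the cluster
   separation; a sample farther than 3 spreads from both centers is
   `ambiguous`. The floor prevents a degenerate (zero-spread) cluster from
   flagging ordinary replicate noise; the median center prevents the
   outlier itself from dragging the cluster toward it.
2. **SNP outlier score** = mean over the 59 SNP probes of the absolute
   distance to the nearest genotype center {0.05, 0.5, 0.95}. This is a
   monotone surrogate for an outlier probability; the downstream linear
   model absorbs its scale. Fixed centers keep the score deterministic; a
   per-probe mixture fit is a possible extension.
3. **Male anchor.** The male Y reference ŷ_M is the median y_norm of the
   lowest-score tertile of males, so contaminated males cannot pollute the
   anchor. Per male, the contamination scale is
   c_Y = clip((1 − y/ŷ_M) / (1 − ŷ_F/ŷ_M), 0, 1), where ŷ_F is the
   inferred-female median y_norm (the Y background). The normalization by
   (1 − ŷ_F/ŷ_M) matters: female DNA does not drive the Y signal to zero
   but to the background floor, and without the correction c_Y measures
   only (1 − ŷ_F/ŷ_M) ≈ 0.9 of the true fraction — a systematic 10%
   underestimate. With a zero background the formula reduces to the plain
   1 − y/ŷ_M.
4. **Score → contamination line.** Ordinary least squares of c_Y on the SNP
   score over all inferred males gives (intercept, slope); females receive
   ĉ = clip(a + b·score). Males (and ambiguous samples, which are
   contaminated males in this workflow) use c_Y directly. Samples pass QC
   iff ĉ < 0.35 (strict).
5. **Genotype matching.** SNP betas are discretized to the nearest center;
   pairwise concordance is the fraction of identical calls. Unrelated
   donors at allele frequency 0.5 expect Σp² = 0.375, versus ≈ 1 within a
   donor, so the 0.80 assignment threshold leaves a wide margin. Donor
   groups are connected components of the ≥ 0.80 graph, checked one-to-one
   against the sample sheet.

**Precision of the estimates.** The male estimate inherits only Y-intensity
noise (per-sample error ~2%). The female estimate inherits the sampling
noise of the discordant-SNP fraction (binomial over 59 SNPs): at c = 0.5
the per-sample sd of ĉ is ≈ 0.065. Recovery checks therefore evaluate the
mean estimate over replicate samples at each contamination level (3 males
and 8 females per level, plus a clean-male anchor cohort), which brings the
per-level error within ±0.05 (males) and ±0.10 (females) across the grid
c ∈ {0, 0.05, …, 0.5}.

## Reference construction

For each cell type, a one-vs-rest two-group ANOVA F is computed per probe
(equal to the squared pooled two-sample t), with direction =
sign(mean_target − mean_rest). The top 50 probes per direction per cell
type are retained (600 for six cell types). Claims are processed in
globally descending F order with ties broken by probe id, which both
assigns a probe wanted by several cell types to the one with the largest F
and backfills the losers from their own ranking in a single pass. The
first-trimester reference augments first-trimester cell samples with term
eSTB and nRBC profiles (those populations are present in early gestation
but profiled at term). No p-value pre-filter is applied before ranking.

## Deconvolution

- **CP** solves min ‖y − Rw‖² s.t. w ≥ 0, Σw = 1 (or ≤ 1) exactly by
  enumerating support sets and verifying primal and dual KKT feasibility —
  for K ≤ ~15 cell types this is faster and sharper than an iterative QP
  and reproduces the noise-free mixture to machine precision. The
  inequality mode first tries unconstrained NNLS and falls back to the
  equality solve when the sum constraint binds.
- **RPC** fits a Huber M-estimate (tuning constant 1.345, 95% Gaussian
  efficiency; IRLS with MAD scale, coefficient-change tolerance 1e-6,
  max 100 iterations), then zeroes negative coefficients and renormalizes
  to the simplex (truncate-then-normalize). A perfect linear fit is
  detected first and returned directly, because the MAD scale degenerates
  at zero residuals.
- **CBS** z-scores the probes with the reference row statistics and fits a
  linear ν-SVR over ν ∈ {0.25, 0.5, 0.75} (C = 1, tol 1e-6), keeping the ν
  whose fit has the lowest RMSE. Row-centering makes the centered signature
  columns sum to zero, so the coefficient vector is identified only up to
  an additive constant; the lost direction is restored by shifting the
  coefficients to sum to one — the constraint mixture weights satisfy —
  before truncation and renormalization. Without this shift, noise-free
  recovery is impossible in principle; with it, recovery is ~1e-7.

Probes missing in a sample are dropped per sample; matrix-level
deconvolution requires ≥ 50 usable reference probes per sample.

## In-silico benchmark

Proportions are drawn by the recursive-uniform scheme — q₁ ~ U(0,1),
qⱼ ~ U(0, qⱼ₋₁) — which biases later positions small; the block is repeated
once per cell type with the starting position rotated, and rows are
normalized onto the simplex (the draws need not sum to one). 250 rows per
rotation × 6 rotations = 1500 mixtures. Mixtures are assembled from one
randomly chosen donor sample per cell type (injecting biological replicate
noise into the mixture itself); mixing per-cell-type means instead is a
flag. A draw-(K−1)-plus-remainder variant (discarding negative remainders)
exists as `mode="remainder"` but is not the default. Metrics per cell type:
R² (squared Pearson correlation — not 1 − SSE/SST), RMSE, MAE, mean bias,
plus pooled versions. For exactly-sum-to-one estimators the per-cell-type
biases cancel by construction.

## Differential methylation

Each probe gets an OLS two-group fit (one cell type vs the pooled remaining
cell samples, villi excluded; or term vs first trimester within a cell
type): Δβ = mean difference, s² = residual mean square on d_g = n − 2 df,
v = 1/n₁ + 1/n₀. Variance moderation uses the log-variance moment scheme:
e_g = log s²_g − ψ(d_g/2) + log(d_g/2); d₀ solves ψ′(d₀/2) = var(e) −
ψ′(d_g/2) via Newton on the trigamma inverse (sample variance, ddof = 1;
mean trigamma when residual df vary across probes); if the right side is
≤ 0, d₀ = ∞ and s₀² is the mean of s²_g, otherwise s₀² = exp(mean(e) +
ψ(d₀/2) − log(d₀/2)). Posterior variance s̃²_g = (d₀s₀² + d_gs²_g)/(d₀+d_g);
t = Δβ/(s̃√v) on d₀ + d_g df. With equal per-probe df this estimator agrees
with the Bioconductor reference implementation to 1e-14 (cross-checked in
the test suite via Rscript); forcing d₀ = 0 recovers the ordinary pooled
two-sample t, and d₀ = ∞ the fully shrunken statistic. Probes with zero
residual variance are excluded from hyperparameter estimation but still
receive (shrunken) statistics.

Calls are strict: DMC ⇔ Bonferroni-adjusted p < 0.01 ∧ |Δβ| > 0.25
(cell-specific) or > 0.05 (gestational). Bonferroni multiplies by the
number of probes tested within that comparison. Direction is the sign of
Δβ ("less"/"more" for one-vs-all, "decrease"/"increase" for term vs first).

Enrichment uses the 2×2 Pearson chi-squared without continuity correction
(the tables are large; the correction is negligible and the plain statistic
matches the hand formula exactly). The background frequency is the fraction
of **all tested probes** in the element — not of DMCs — and fold =
observed/background; Bonferroni spans all element × comparison × direction
rows tested in one analysis. The promoter summary counts, per gene, the
promoter probes that are a DMC for at least one cell type, with a
mean-fraction-by-probe-count background curve smoothed by a centered
3-point running mean.

**Recovery bookkeeping.** PMD and imprint probes carry genuine planted
cell-type differences (that is their purpose), so the one-vs-all caller
flags them correctly even though they are not planted "DMC" probes. The
recovery confusion matrix is therefore computed over probes whose
cell-specific DMC truth is defined (baseline, planted-DMC, gestational and
repeat probes); counting the region-feature probes as false positives would
mislabel true biology.

## Region summaries

- **PMDs**: probes flagged PMD, minus CpG-island, shore and promoter probes
  (the array over-covers those contexts); per (cell type, trimester), probe
  means across samples are binned into [0, 0.2), [0.2, 0.4), [0.4, 0.6),
  [0.6, 0.8), [0.8, 1.0] — lower-closed, last bin closed — and reported as
  percentages summing to 100.
- **Imprints**: per (cell type, trimester, category), the fractions of
  probe means below 0.25, inside the closed [0.25, 0.75] band (the
  monoallelic-methylation signature), and above 0.75; the three partition
  the probes. The boundary convention (closed band) is a documented choice.
- **Repeats**: per-sample means over the Alu set, LINE1 set and all probes;
  per trimester and probe set, a linear model of the per-sample means on
  the cell-type factor with villi as reference yields each cell type's mean
  difference and two-sided p. Contrasts use per-sample summary means, not
  per-probe models, and donor pairing is not modelled.

## Problem sizes and determinism

Default study conditions: 20,000 probes, 6 cell types × 10 donors × 2
trimesters plus 4 villi per trimester (128 samples), 500 hypo + 300 hyper
planted DMCs and 100 gestational DMCs per cell type, 20 PMD blocks × 40
probes, 200 imprint and 600 repeat probes, 59 SNP probes. The test suite
runs scaled-down versions of the same conditions (4,000 probes, 6
replicates) for unit-level checks and the full defaults for end-to-end
recovery; the contamination sweep uses a single-cell-type cohort (700
probes) since only SNP probes and intensities matter there. All randomness
flows through explicit integer seeds; regenerating with the same seed is
bit-identical.

## Known limitations

- The SNP outlier score saturates as admixture approaches 50% on
  adjacent-genotype SNPs (the mixed beta approaches the midpoint between
  centers, where symmetric noise folds the distance downward), so a single
  linear calibration mildly underestimates the largest contamination
  fractions; estimates remain monotone in the true fraction.
- eSTB and TB signatures are similar in real tissue; the generator plants
  them as distinct as any other pair, so synthetic benchmarks do not probe
  the TB/eSTB identifiability limit real villi present.
- One-vs-all contrasts pool all non-target cell samples, so the "rest"
  group mixes heterogeneous populations; the moderated model treats it as
  one group, as the analysis it reproduces does.
- Gestational-age calls at the default conditions (10 donors per trimester,
  +0.10 shifts, Bonferroni over 20k probes) run at ≈ 0.9 power; called
  directions are exact.
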