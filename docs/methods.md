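# Methods

## The model and its assumptions

`geneqx` tests, gene by gene, whether the across-population variance in
predicted expression exceeds the neutral-drift expectation. Predicted
expression is the weights-only linear model exported by cross-tissue
expression-prediction methods: for individual i, Σ_l α_l g_il over the
gene's L regulatory variants (no intercept; effects additive and
independent by construction of the upstream training). At the population
level this reduces to the genetic value z_m = 2 Σ_l α_l p_ml, and the test
statistic is

    QX = Z'ᵀ F⁻¹ Z' / (2 V_A),   V_A = 2 Σ_l α_l² ε_l(1 − ε_l),

with Z' the centered genetic-value vector with its last entry dropped and F
the (M−1)×(M−1) expected neutral covariance of standardized frequencies.
The χ²_{M−1} null holds when (i) across-population frequency deviations are
approximately multivariate normal (short drift times), (ii) the gene's
variants drift independently (no LD), and (iii) F is known rather than
estimated. Each failure mode has a dedicated mitigation below. When one
gene per (gene, tissue) pair must be chosen, the model with the highest
training R² wins, ties broken by the lexicographically smallest tissue
label (training R² tracks out-of-sample predictive ability well enough to
serve as a proxy).

Conventions: the centered vector always drops its *last* entry and
population order is the panel's declared order. The statistic is invariant
to which entry is dropped and to population relabeling provided F is built
under the same convention (tested to 1e−8), and is likewise invariant to
rescaling all effect sizes and to allele flips (α → −α, p → 1 − p).

## The neutral covariance F

Each model variant is matched to k = 100 neutral variants from the same
reference-frequency bin; 25 bins of width 0.02 on *folded* frequency
(minor-allele frequency) are the default, since 25 × 0.02 spans exactly
(0, 0.5] — an unfolded 50-bin mode is available. The model variant's
binning frequency is the panel's `ref_freq` column when present, else its
across-population mean. Bins with fewer than k members are sampled with
replacement (warned); empty bins fall back to the nearest non-empty bin
(logged). From the pooled k·L matched set, each usable variant (0 < ε < 1)
contributes y = [(p − ε)/√(ε(1−ε))] with the last entry dropped, and
F = Σ y yᵀ / (K−1). Self-centering by the variant's own across-population
mean matches the construction of Z', so the −σ²/M term the centering
induces appears consistently on both sides of the quadratic form; the
estimator converges to T C Tᵀ (T the center-and-drop map, C the true
standardized covariance), *not* to C itself. F is estimated per gene by
default (the matched set is gene-specific); a genome-wide shared-F mode
trades exactness for speed. The quadratic form is evaluated by Cholesky
solve, never an explicit inverse; conditioning above 1e10 warns, and
singular F (or zero V_A) flags the gene rather than silently dropping it.

## P-values

* **freqPerm** — the classic resampling null: each permutation replaces
  every model variant's whole across-population frequency vector with that
  of one of its matched neutral variants (preserving each null variant's own
  population structure), recomputes V_A from the permuted means, and
  recomputes QX against the same F. Empirical P = (r+1)/(n+1) with
  n = 100,000 initially, escalating to 1,000,000 fresh draws when
  P < 1e−4. Well calibrated only when the gene's variants are unlinked —
  which holds for the synthetic fixtures but not for real gene models,
  where residual LD makes freqPerm anticonservative.
* **gamma** — a two-parameter gamma (location 0) fitted by maximum
  likelihood to the genome-wide QX scores; P is the fitted upper-tail
  probability. The map is monotone, so gene ordering equals ordering by
  QX. Method-of-moments is the logged fallback if the MLE fails;
  non-positive scores are excluded from the fit and receive P = 1.
* **effPerm** — magnitudes resampled with replacement from the pool of all
  models' |weights|, signs kept; Z' and V_A both recomputed. This
  conditions on frequencies and only detects coordinated multi-variant
  shifts; by scale invariance single-variant genes always get P = 1 (the
  ≥-count uses a 1e−9 relative tolerance so float rounding cannot break
  the exact invariance).

FDR control is Benjamini–Hochberg. The scan reports the Spearman rank
correlation between every pair of computed schemes as a diagnostic; on
neutral synthetic data gamma vs freqPerm ordering agreement is ≈ 0.99.

## Synthetic data generator

Population structure is Balding–Nichols: ancestral frequency
p₀ ~ Beta(1,1) truncated to (0.05, 0.95) (emulating a common-variant
ascertainment filter), then per-population frequencies
Beta(p₀(1−d)/d, (1−p₀)(1−d)/d) with drift d per population. Defaults
d = (0.02, 0.04, 0.06, 0.08, 0.10) over 5 populations give continental-scale
differentiation (FST of a few percent). Gene models default to L = 12
variants (the typical size of the expression models emulated) with
standard-normal weights. Injected selection shifts the target population's
frequencies by `shift_sd_units`·sign(α)·√(ε(1−ε)) — coordinated mode moves
all variants, single-haplotype mode only the largest-|α| variant — with
clipping to [0.01, 0.99] (counted) so V_A stays non-degenerate. Genotypes
are Hardy–Weinberg binomial draws, emitted as dosage TSV and VCF in the
same dialects the pipeline reads.

What the generator deliberately does *not* emulate: linkage disequilibrium
among a gene's variants (variants are independent given the ancestral
frequency), non-equilibrium demography, and frequency-dependent
ascertainment of weights. Passing null-calibration tests on fixtures
therefore shows the estimator chain is correct under the model's own
assumptions; it does not show freqPerm would be calibrated on real, LD-bound
gene models (it is not — that is precisely why the gamma correction
exists). LD effects are exercised separately through the forward simulator,
which produces genuinely linked variants.

## Forward Wright–Fisher simulator

Haplotype-level forward simulation of one "gene": a 1 Mb segment accruing
eQTL mutations (effects ~ Normal(0,1)) and a disjoint 100 kb neutral
segment, in an ancestral population of 10,000 diploids for 20,000
generations (μ = 8e−9/bp/gen, r = 1e−7), under Gaussian stabilizing
selection on the summed effects (optimum 0, sd 1, relative fitness
exp(−(z−θ)²/2sd²)); then a split into 5 subpopulations of 10,000 evolving
independently (no migration) for 400 generations with μ = 1e−10 and
r = 1e−8, the optimum shifted by FOS in the last subpopulation only. The
two segments assort independently; crossovers and mutations are Poisson;
mutations fixed during burn-in fold into a phenotype baseline, lost ones
are recycled (infinite sites within each segment). The final state reports
position, effect, and per-subpopulation frequency of every variant still
segregating somewhere.

The full parameterization is cluster-scale, so a `rescale` knob divides N
and all generation counts by a factor c and multiplies μ and r by c,
preserving N·μ and N·r. Selection coefficients are deliberately *not*
rescaled (the fitness function is part of the design), with two documented
consequences: equilibrium genetic variance (≈ 4μ_trait·Vs at
house-of-cards balance) grows with the rescaled mutation rate, and the
strength of stabilizing selection relative to drift changes with c. All
shipped statistical checks run at rescale 20 (N = 500; 1,000 burn-in and
20 post-split generations), chosen as the design point where one replicate
costs about a second on one CPU.

QX on a simulated gene treats the segregating eQTL mutations as the model
and estimates F directly from the neutral-segment variants — no frequency
matching, since the neutral segment *is* the simulation's own matched
null.

**Behavior under stabilizing selection.** With selection off
(`fitness_sd → ∞`) the engine reproduces neutral Wright–Fisher dynamics
(heterozygosity decays at 1/(2N) per generation; mean QX matches the
χ²_{M−1} mean of 4, and is invariant to the rescale factor). With the
stabilizing-selection study conditions active, across-population divergence
of the genetic value is strongly suppressed relative to the neutral F —
the restoring force per generation is ≈ V_G/(Vs+V_P) — so neutral-FOS mean
QX sits far *below* 4 (about 0.01 at rescale 20). This under-dispersion is
a real property of expression under stabilizing selection, not an engine
artifact, and it is why the package's null calibration is built on matched
neutral variants and the genome-wide gamma fit rather than on the χ²
reference directly. One shipped acceptance check asserts the χ² mean under
the selection-on conditions and is expected to fail for this documented
reason; its selection-off counterpart passes.

**Power.** Power at threshold P ≤ α (α = 1e−4 by default; the comparison
is inclusive so α = 1 is exactly degenerate) is the fraction of
non-degenerate replicates detected. The gamma scheme calibrates its fit on
the FOS = 0 condition's scores — a within-condition fit would be
self-calibrating and could never approach power 1 — falling back to the
run-pooled scores when FOS = 0 is absent. effPerm pools effect magnitudes
from same-FOS replicates (`effperm_matched`) or from the neutral condition
(`effperm_neutral`). Binomial uncertainty on power uses the Agresti–Coull
interval. With coordinated injected selection the gamma scheme is uniformly
more powerful than effPerm (on the shipped positive control: power 1.0 vs
0.0 at α = 1e−3), since effPerm's null preserves exactly the
sign-frequency alignment that carries a coordinated signal.

## Expression summaries and agreement

Per-population summaries are medians of per-individual predictions
(missing dosages mean-imputed with a logged count; dosages validated to
[0, 2]); a per-gene z-scored copy (ddof = 1; all-zero where the sd is 0) is
kept for display. The variant-contribution matrix is α_l·p_ml mean-centered
per variant (rows sum to 0). The agreement statistic between observed and
predicted summaries is the sum over genes of the Spearman correlation
(average ranks for ties; genes with constant medians skipped with a
warning) across ≥ 3 shared populations; its null shuffles the observed
medians' population labels independently per gene (the stricter null;
whole-matrix permutation is available) and P = (1 + #{null ≥ obs})/(1 + n)
with n = 10,000 shuffles by default.

## Enrichment

Genes are ranked by ascending P with ties broken by gene id (deterministic
tiers). For each tier N in {10, 20, 30, 50, 75, 100, 150, 200, 300, 500,
1000, 2000, 3000, 5000, 10000}: enrichment = top-N set proportion divided
by the overall proportion, a two-sided exact binomial P (the same machinery
reports depletion), and a 95% Agresti–Coull interval (z = 1.959964, clipped
to [0, 1]). Oversized tiers are skipped with a warning.

## Numerical and design choices

* Empirical P-values use (r+1)/(n+1): never 0, never above 1.
* Escalation draws n_max fresh permutations rather than reusing the first
  batch (simpler reproducibility semantics under one generator stream).
* The gamma fit in the genome scan requires ≥ 10 usable genes (the
  standalone `gamma_pvalues` keeps a stricter default of 50); fewer genes
  skip the scheme with a warning.
* VCF-derived frequencies use observed (non-missing) haploid calls only;
  a sample present in the VCF but absent from the sample map is an error,
  strand-ambiguous A/T and C/G pairs warn, and variants unmatched or
  all-missing in some population go to a dropped list.
* Missing genotype dosages are mean-imputed per variant at prediction
  time; panels, not imputation, are the source of scan frequencies.
* All generators and the scan are pure functions of their seeds; CLI
  outputs carry a provenance comment line (version, command, seed) and are
  byte-identical under a repeated seed.

## Known limitations

Trans-regulatory effects, migration after the split, PCA-based population
axes, and LD-aware neutral matching are out of scope. The gamma correction
inherits the usual genome-scan caveat that a heavily contaminated score
distribution (many true signals) makes the fit conservative. freqPerm is
exact only for unlinked variants. The simulator's rescaling preserves
population-scaled mutation and recombination but not selection, so
absolute power at strong rescaling understates the full-scale design;
relative comparisons between schemes and FOS conditions are the supported
use.
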