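# Methods

## Design

Three stocks — two parents (NL, AR) and their hybrid (HY) — with r
replicates each (default 3), measured as gene-level and miRNA-level count
matrices. Four contrasts drive everything downstream: the parental contrast
NL vs AR, the two hybrid-vs-parent contrasts, and the hybrid vs the
mid-parent value (MPV), the arithmetic mean of the parents.

## Differential expression

The test is a deliberately small, transparent negative-binomial Wald test;
it is not intended to replicate any specific DE package numerically, and its
acceptance surface is category *fractions*, not per-gene identities.

1. **Normalization.** Median-of-ratios size factors: a pseudo-reference is
   the per-feature geometric mean over samples (features observed in every
   sample only); each sample's factor is the median log-ratio to the
   reference, exponentiated, rescaled to geometric mean 1. If no feature is
   observed everywhere, column totals are used (with a warning). This
   estimator assumes **most features are unchanged between samples**; worlds
   violating that (e.g. simulations where every feature is differential)
   will absorb real signal into the factors. The generator's default mix
   (~78 % conserved) satisfies the assumption.
2. **Dispersion.** Var = μ + φμ². Per feature,
   `φ_raw = max(0, (s² − μ̄)/μ̄²)` from the pooled within-group variance
   (df = n_total − n_groups) and the overall mean of normalized counts,
   shrunk toward the global median of φ_raw over expressed features with
   weight `w = n/(n+4)` where n is the per-group replicate count (w = 3/7 at
   three replicates). The heavier shrinkage (vs. using total sample count)
   is what keeps the normal-reference Wald test calibrated at r = 3: the
   realised null p < 0.01 rate is ≈ 0.026 (w = 3/7) vs ≈ 0.032 (w = 0.6).
   The shrinkage target is a single global median, not a mean-dependent
   trend; at the simulated mean range (≥ 200) the Poisson term is small and
   a mean-binned trend changes nothing measurably.
3. **Wald test.** With pseudo-counted group means m_g = mean_g + 0.5,
   `z = ln(m_a/m_b) / sqrt((1/m_a + φ)/n_a + (1/m_b + φ)/n_b)`, two-sided
   normal p. All-zero features get p = 1, log2fc = 0. Known behaviour: at
   r = 3 the test is mildly anticonservative (≈ 2× nominal at the 0.05
   level, ≈ 2.6× at 0.01); the fold-change gate removes nearly all
   remaining null calls at the gene thresholds.
4. **Calls.** Genes: p < 0.01 and fold > 2 or < 0.5. miRNAs: p < 0.05 only.
   Raw p by default (the study convention); BH-adjusted values are always
   reported and can gate instead (`use_bh`). The test runs on size-factor
   normalized counts by default; a `de_input="tpm"` flag preserves the
   literal run-on-TPM reading for comparability, but count-based testing is
   the statistically coherent default.

## Mid-parent (non-additivity) test

Pseudo-MPV samples `m_r = (x_NL,r + x_AR,r)/2` are built on normalized
counts, pairing parental replicates by index (with pooled replicates there
is no natural pairing; index pairing is a deterministic, documented choice;
unequal parental replicate numbers truncate to the shorter). HY replicates
vs pseudo-MPV samples are tested with the same Wald machinery; p < 0.05
(configurable `mpv_p`; the threshold is not stated in the source studies)
flags the feature non-additive (NEG/NEM). The pseudo-MPV group is not
itself NB-distributed — the averaged variance is smaller — but the moments
dispersion is estimated from the realised group variances, so the variance
model tracks it.

## Pattern classification

Evaluated top-down per feature, first match wins (P = NL vs AR,
H_N = HY vs NL, H_A = HY vs AR, M = HY vs MPV; "sig" means the feature-type
call, including the fold gate for genes):

1. **ELOD up** — H_N and H_A significant, both up. Sub-bin by parental
   relation: VII (NL > AR), VIII (parents statistically equal), IX
   (NL < AR).
2. **ELOD down** — both significant down → X / XI / XII, same sub-order.
3. **ELD-NL** — P sig, H_N not sig, H_A sig, **and mid-parent evidence**:
   M sig or p_M < p_{H_N}. III if NL > AR else IV.
4. **ELD-AR** — mirror image (V if AR > NL else VI), evidence
   M sig or p_M < p_{H_A}.
5. **Additive** — P sig and M not sig. I if NL > AR else II.
6. **Conserved** — nothing significant. 7. **Ambiguous** — everything else.

`non_additive` (the NEG/NEM flag) is true for any ELD/ELOD feature and for
any feature with M significant regardless of category.

**Why the mid-parent evidence condition exists.** An additive feature with a
4-fold parental difference sits at fold ≈ 1.6 against its nearer parent.
At φ = 0.05 and three replicates the Wald z for that contrast saturates
near 2.6 — a coin flip at p < 0.01 — so without the condition roughly half
of all truly additive features present the dominance signature (P sig, one
hybrid contrast ns, the other sig) and land in ELD before the additive rule
is reached; in the deterministic regression mode, with the fold gate
blocking the fold-1.6 contrast, *all* of them would. Requiring a
significant M instead would cap dominance recovery at the MPV test's power
(≈ 0.8 at these settings). Comparing the two p-values resolves the
undecided cell toward whichever departure — from the matched parent or from
the mid-parent — the data support more strongly: with it, ≥ 94 % of true
dominance/overdominance features and ≈ 93 % of true additive features are
recovered, and group fractions land within one point of those configured.

Other conventions: sub-bins and the ELOD definition (significant against
*both* parents) are fixed as above for determinism and NL↔AR symmetry
(relabelling the parents maps I↔II, III↔V, IV↔VI, VII↔IX, X↔XII). Ambiguous
is kept as its own bin rather than folded into any printed group. miRNAs use
the identical classifier under the DEM thresholds; fewer observed categories
among miRNAs is an outcome, not a different scheme.

**Summaries.** Group percentages use the categorized total (sum over I–XII)
as denominator; within-group statistics report the larger bin's share and
the larger:smaller ratio; the ELOD pair is compared the same way.
Percentages are rounded half-up to 1 decimal, ratios to 2 — the printed
style of the tables these summaries mirror. The non-additive total is the
ELD + ELOD sum.

## Negative miRNA–mRNA network

A candidate pair from the (externally supplied or simulated) target table is
retained iff both members are significant in at least one shared
hybrid-vs-parent contrast with opposite directions. Replicate-level
correlation is deliberately not used (unstable at r = 3). A pair negative in
one contrast and concordant in the other is retained, annotated with the
supporting contrast(s); reported directions come from the first supporting
contrast in the fixed order (HY_vs_NL, HY_vs_AR) — "gene up-regulated"
therefore means up relative to the parent of that supporting contrast, a
documented convention, not a claim about any particular study's definition.

## Enrichment

Upper-tail hypergeometric p = P[X ≥ k] with X ~ HG(N, K, n), exact via the
survival function; BH across tested pathways; the default filter is raw
p < 0.05. Background = annotated genes, intersected with the
expressed-feature list when provided (the pipeline passes all features with
any nonzero count). Set members outside the background are clipped and
counted, not fatal.

## Growth metrics

WGR/BLGR/BDGR are relative gains (%) of weight, body length and body depth;
SGR = 100·(ln Wt − ln W0)/t (%/day). All are unit-scale invariant; records
with non-positive measurements or durations are rejected. Stock summaries
report mean ± sample SD per metric and the HY/parent mean ratios. A Welch
t-test between stocks is offered as a descriptive convenience only (the
multiple-comparison procedure of the motivating experiments is out of
scope).

## Synthetic data

The generator states a world, not a tuning surface:

* 3 stocks × 3 replicates; 13 000 genes, 300 miRNAs by default.
* Baseline (low-parent) means log-uniform in [200, 2000]; pattern means per
  label: additive — parents 4-fold apart, hybrid at the MPV; ELD — hybrid
  equal to one parent, parents 4-fold apart; ELOD — hybrid 4-fold above the
  higher (or below the lower) parent. Effect size 4 and φ = 0.05 follow the
  liver RNA design the package emulates; the default label mix (~77.9 %
  conserved; additive 10.7 %; ELD-NL 6.1 % split ≈ 2:1; ELD-AR 4.5 % split
  ≈ 1.2:1; ELOD up 0.55 % / down 0.28 %) reproduces the published category
  proportions of that design at the printed ratios.
* Labels are apportioned by largest remainder (exact configured fractions,
  ties by label order) and shuffled under the seed.
* Counts are NB(μ·library factor, φ), library factors uniform ±20 % per
  sample so normalization is genuinely exercised; φ = 0 degenerates to
  Poisson; optional per-feature gamma jitter of φ (off by default).
* `mean_injection=True` replaces sampling with rounded expected counts and
  equal library factors — a zero-noise mode existing solely for exact
  regression tests.
* Target tables: per miRNA, a configurable fraction of rows is constructed
  negatively regulated (partner gene truly opposite in a contrast where the
  miRNA truly departs at full effect size); the rest are uniform random
  genes. miRNAs with no strong hybrid direction cannot honor the negative
  fraction and contribute only random rows (rows carry an `is_negative`
  truth flag).
* Phenotypes: weight exponential at the stock SGR, length/depth linear,
  lognormal measurement noise (log-sd 0.08). Default SGRs
  (HY 2.77, NL 2.18, AR 1.90 %/day) encode the reported day-45 hybrid
  advantage ratios (1.27× and 1.46×) at juvenile-tilapia growth magnitudes.

**What a green test does not establish.** The generator draws independent
features — no correlation structure, no compositional coupling beyond the
library factor, no GC/length biases, no pooling of individuals below the
replicate level (the study design pools six livers per replicate; the
generator exposes φ directly rather than modelling pooling's variance
shrinkage) — and its miRNA targeting is tabular, not sequence-based. Tests
green on this world certify the pipeline's arithmetic and statistical
behaviour, not robustness to those real-data features.

## Numerical conventions

Printed percentages round half-up to 1 decimal, ratios to 2. Empty
denominators yield 0.0 (or an infinite ratio when only the larger bin is
populated). All randomness flows from one integer seed through split
sub-streams, so adding one stochastic stage does not perturb the others;
identical seeds reproduce outputs byte-identically.

## Known limitations

* The Wald test's small-sample anticonservativeness (above) is documented,
  not corrected; exact DE-package replication is out of scope.
* Median-of-ratios normalization requires a majority of unchanged features.
* The additive/dominance boundary is intrinsically soft at three
  replicates; the p-value-comparison tie-break is a calibrated convention,
  not an inference with controlled error rates.
* Hybrid-vs-parent direction conventions in the network stage are a
  documented choice; alternative parent references change the
  "% up-regulated" statistic.
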