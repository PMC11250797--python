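# Methods

## The score

The PRC2-AgeIndex of a sample is the average DNA methylation inside a fixed
reference set of genomic regions: the K low-methylated regions (LMRs) most
strongly bound by PRC2 (EZH2/SUZ12 ChIP signal) in embryonic stem cells,
K = 1000 by default. The premise is empirical: during aging of mitotic
somatic cells, methylation is gained preferentially and consistently inside
PRC2-bound LMRs while the genome-wide background loses methylation, so the
mean beta over that set rises monotonically with age in every assay that can
measure it. The score involves no fitting and no training data; all modelling
in this package happens upstream, in how the reference set is constructed.

Two weightings of "average" are implemented because the choice is genuinely
open: `pooled_cpg` (default) averages the betas of every covered CpG inside
the set, which is robust to region-size variation and to sparse assays;
`region_mean` averages per-region means, which weights a 500 bp island the
same as a 10 kb one. Every result records which was used. Regions without a
single covered CpG are excluded, never imputed, and their count is reported —
with single-cell data most regions are partially covered and silent
imputation would hide that.

## LMR segmentation

LMRs are segmented with a two-state HMM over consecutive CpGs of a
count-based methylome (states: hypomethylated island vs methylated
background). Design choices:

- **Emissions** are beta-binomial on (methylated count, coverage),
  parameterised by mean `mu` and concentration `conc` per state. Bisulfite
  counts are overdispersed relative to binomial (cell-to-cell heterogeneity,
  allele effects), and a binomial emission makes the decoder overconfident at
  high coverage.
- **Fitting** is Baum–Welch EM, shared across the genome. The transition and
  start updates are the exact maximisers; the emission update is a
  Nelder–Mead ascent started from the previous parameters, so every step is a
  generalised EM step and the log-likelihood trace is non-decreasing (a unit
  test asserts this to 1e-8). The beta-binomial likelihood is evaluated on
  the unique (count, coverage) pairs only, which makes EM run in seconds on a
  100 k-CpG chromosome.
- **Stopping**: absolute change in total log-likelihood below `tol` (default
  1e-4) or `max_iter` (100); non-convergence warns and uses the best iterate.
  On well-separated data EM converges in a handful of iterations.
- **Chains** break wherever consecutive CpGs are more than `desert_size`
  (default 1000 bp) apart, so CpG deserts never transmit state information.
- **Decoding** is posterior (forward–backward) with a 0.5 cut rather than
  Viterbi: posterior decoding gives smoother, testable boundaries, and the
  per-CpG posterior is useful diagnostics; Viterbi is available as an option
  and agrees with posterior decoding on clean signal.
- **Reported regions** are maximal low-state runs with at least `min_cpgs`
  (default 10) CpGs, anchored on CpG coordinates (end = last member CpG + 1).
  The CpG-count filter is the load-bearing stability filter; no separate
  significance test is applied.
- **Label symmetry** is resolved after fitting: the low state is whichever
  fitted state has the smaller emission mean. If the fitted "low" mean is not
  actually low (`max_low_mean`, default 0.5), the two states have collapsed
  onto a uniformly methylated genome, no hypomethylated compartment exists,
  and the caller reports nothing rather than half-splitting noise.
- **Initialisation** is fixed and documented (means 0.1/0.8, concentrations
  10, self-transition 0.95), no random restarts — segmentation is
  deterministic given the input.

Array and single-cell methylomes are rejected by the segmenter: without read
counts, or with binarised coverage-1 observations, the emission model is
meaningless. Those assays use the site-level path below.

## PRC2 ranking and selection

Each region's binding score per ChIP factor is the base-length-weighted mean
of the factor's piecewise-constant signal over the region, with uncovered
bases contributing the track's background value — 0 for fold-change tracks
(pipelines omit unenriched intervals), 1 for p-value tracks (no evidence).
The region's PRC2 score is the unweighted mean across factors. Both
semantics are supported because both conventions occur in practice; a
selection must declare which it uses, and mixing them is an error. For
p-values the combination is deliberately the plain mean (the "lowest average
p" rule), not a Fisher-style combination.

Regions overlapping a blacklist interval by one or more bases are removed
before ranking. Ties in the top-K selection break by genomic coordinate, so
membership is invariant to input order.

**Site-level path (LMCs).** When regions cannot be segmented (arrays, RRBS,
single cell), individual low-methylated CpGs take their place: sites whose
baseline beta — the mean across one or more reference methylomes — falls
below `low_threshold` (default 0.3; no canonical numeric definition of
"low-methylated" exists, so the default is declared, not derived), ranked by
the single-base track value averaged across factors. For single-cell data a
density filter additionally restricts analysis to neighbourhoods with at
least 10 CpGs/kb on the *reference* CpG landscape: isolated sites covered in
few cells are unreliable, dense islands are where both the signal and the
coverage concentrate.

## Companion statistics

- **Delta**: per-region mean beta difference, old minus young, each mean
  taken over the CpGs covered in that sample; regions covered in only one
  sample are dropped and counted. Coverage-weighting of the region mean is an
  open choice; the unweighted mean is used throughout.
- **Hypermethylated fraction**: proportion of deltas strictly greater than 0.
- **Gain share**: sum of max(delta, 0) over CpGs inside the high-PRC2 set,
  divided by the same sum over all CpGs covered in both samples. This
  positive-part estimator is a declared formalisation of "what share of the
  genome-wide methylation gain happens inside the set". At single-sample
  sequencing depth (~30x) per-CpG deltas are dominated by sampling noise
  whose positive parts accumulate over the ~100-fold larger background, so
  the intended inputs are deep or group-pooled methylomes
  (`io.pool_methylomes` sums read counts across samples, the standard merge);
  with two pooled groups of a dozen 30x samples the estimator is stable.
- **Ranked profile**: regions sorted from least to most bound; a plain moving
  average (window 100 regions, step 10 by default, no kernel) of per-region
  mean betas, skipping uncovered regions. With window = step = N it equals
  the region-weighted index.
- **Group tests**: "one-sided independent t-test" is read as the
  pooled-variance Student test by default (Welch available); identical
  groups give t = 0, p = 0.5 exactly. Confidence intervals, where reported,
  are normal-theory.
- **Outlier rules**: the case-by-case sample removals of practice are
  formalised into two reproducible rules — `anchor_range` (global mean beta
  outside the interval spanned by two anchor samples, e.g. the neonatal and
  centenarian extremes) and `zscore` (|z| > 3 on global means, at least three
  samples), the latter suited to within-group single-sample removals in
  single-cell sets.

## The synthetic-data generator

The generator plants the structure the method assumes and nothing more:

| parameter | default | meaning |
|---|---|---|
| `m_bg0` | 0.85 | background beta at age 0 |
| `m_low0` | 0.05 | LMR beta at age 0 |
| `loss_rate` | 0.001 /yr | global background beta loss |
| `gain_rate` | 0.004 /yr | beta gain in PRC2-target LMRs only |
| `coverage_mean` | 30 | Poisson mean read depth per CpG |
| `dispersion_conc` | 100 | beta-binomial concentration (ICC ≈ 0.01) |
| `chip_noise_sd` | 0.5 | per-factor, per-region ChIP noise |
| `chip_background` | 0.5 | fold-change baseline outside LMRs |
| LMR length | Gamma, mean 3 kb | island size distribution |
| CpG spacing | 1/100 bp background, 1/10 bp in LMRs | density contrast |
| target strength | N(8, 1.5) | ChIP enrichment of PRC2 targets |
| non-target strength | N(1, 0.3) | ChIP enrichment of other LMRs |

Age effects are linear with clamping to [0.01, 0.99] — the simplest structure
consistent with monotone aging trends — so every planted quantity has a
closed form (a target LMR at age 50 has true beta 0.05 + 0.004·50 = 0.25).
LMRs are placed one per equal-width slot at a random offset, which guarantees
disjointness and seeded reproducibility; layout and samples take explicit
seeds, so adding a sample never perturbs an existing one. ChIP strengths and
noise are sized so that factor scores correlate with the planted truth at
r ≈ 0.95 and the target/non-target gap (≈ 7) is many times the noise —
mirroring how cleanly ESC EZH2/SUZ12 peaks separate from background.

Downsampling emulates assays structurally, not mechanistically: `array`
keeps a random ~1.5% of sites and carries betas only (counts are never
fabricated); `rrbs` keeps CpG-dense neighbourhoods preferentially (no
in-silico restriction digestion — there is no genome sequence in scope);
`single_cell` keeps a small site fraction and binarises each kept CpG
(Bernoulli(beta), coverage 1).

**What passing tests do and do not show.** The generator produces idealised
data: homogeneous cell populations, uniform coverage, no bisulfite-conversion
error, no mapping artefacts, no batch effects, no tissue heterogeneity, and
an exactly linear age effect confined to a known subset. Recovery there
demonstrates the pipeline's correctness — that each stage computes what it
claims and the stages compose — not that real tissues will show Jaccard 1.0
or r > 0.99 with age; published effect sizes (e.g. per-region deltas of
0.05–0.08 over a lifetime in real tissues) are smaller and noisier than the
planted ones.

## Desk-scale study sizes

The built-in evaluations run two seeded studies: a segmentation-scale study
(one 10 Mb chromosome, 50 planted LMRs, 30% targets, coverage 30 — ~113 k
CpGs) and an index-scale study (5 Mb, 60 LMRs, 25% targets) carrying an
age series 0–100, young/old groups of six, and 12-sample cross-assay
comparisons. The gain-share evaluation pools 12 replicates per age group
into group methylomes, the estimator's intended use. These sizes preserve
the ratios that matter (background-to-island CpG counts, target fraction,
depth) at a scale where the whole pipeline runs in seconds.

## Known limitations

- The segmenter fits one genome-wide emission model; methylomes with strong
  chromosome-scale heterogeneity (e.g. large partially methylated domains)
  would violate the two-state assumption — PMD detection is out of scope.
- bedGraph is the signal interchange format; bigWig input is not parsed.
- The LMC threshold (0.3) and single-cell density cut (10 CpGs/kb) are
  declared conventions, not estimated quantities.
- No multiple-testing correction is applied across tissues or comparisons;
  reported p-values are raw, per comparison.
- Non-CpG methylation contexts are ignored throughout.
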