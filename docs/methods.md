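# Methods

## The problem

Most disease-associated variants are non-coding, and a plausible mechanism
for many of them is the creation or destruction of tissue-specific enhancer
activity by a single base change.  `esnpscan` implements a pipeline that
ranks biallelic SNVs by their predicted effect on enhancer activity:

1. train a sequence-based classifier of enhancer windows,
2. calibrate an activity threshold tau at a fixed false-positive rate,
3. score every SNP's reference and alternate alleles across a battery of
   sliding windows and summarize the effect with the *essential window
   number* (EWN),
4. select candidate SNPs by population allele-frequency criteria (MAF,
   F_ST, EA-major orientation),
5. corroborate calls with allelic-imbalance tests on heterozygous-site read
   counts and with motif enrichment at calibrated PWM thresholds,
6. aggregate risk alleles into a polygenic risk score (PRS) evaluated by
   control-quantile enrichment.

Every stage runs against synthetic data generated by the package itself, so
the full pipeline is testable offline.

## Enhancer scorer

The scorer is a 1-D convolutional network over one-hot DNA (A,C,G,T rows;
N encodes as uniform 0.25), implemented in NumPy: stacked
convolution/ReLU/max-pool layers, a dense ReLU layer, and a sigmoid output
in [0,1].  Training is minibatch Adam on binary cross-entropy with a seeded
70/15/15 train/validation/test split, early stopping on validation loss
(patience 5), and symmetric reverse-complement augmentation of both classes.
All randomness (split, initialization, shuffling, dropout) flows from one
seed, so training is bit-reproducible.

Two architecture profiles ship with the package:

* **Full scale** (`ModelConfig()` defaults): 1 kb input, five convolution
  layers with 320/320/240/240/480 kernels (width 8), max-pooling 4/4/5/5/1,
  and a 180-unit dense layer.  Pooling truncates remainders; the
  configuration validator only requires every layer's output length to stay
  positive, since convolution already shrinks the sequence and exact
  divisibility is unattainable for most kernel/pool combinations.
* **Desk scale** (`ModelConfig.desk_scale()`): 200 bp input, two
  convolution layers (32 and 48 kernels of width 8) with *global* max
  pooling before the dense head (32 units).  Global pooling is the standard
  inductive bias for motif-presence problems — an enhancer is defined by
  containing binding sites, not by where they sit — and at desk-scale data
  volumes it is decisively better: the local-pool stack plateaued at chance
  on the planted-motif benchmark, while the global-pool profile reaches
  held-out auROC ≈ 0.98 in about 30 epochs.

At inference the reported score is the mean of the forward-strand and
reverse-complement outputs, which makes `score(s) == score(revcomp(s))`
exact by construction.

**Activity threshold.** `calibrate_threshold` sets tau to the smallest
observed negative-sequence score at which the empirical false-positive rate
is at or below the budget (default 1%).  It requires at least `1/fpr`
negatives so the empirical rate has resolution at the budget.  "Active"
means score ≥ tau everywhere in the package.

## Sliding windows and the essential window number

A SNP's effect depends on where a putative enhancer sits relative to it, so
the scorer is applied at every window whose center lies within ±`span` bp of
the SNP, stepping by `stride` (defaults: 1 kb windows, stride 20 bp, span
±200 bp — 21 windows).  For each window the delta is the alternate-allele
score minus the reference-allele score.  EWN(gain) counts windows with
ref < tau ≤ alt; EWN(loss) counts alt < tau ≤ ref (conversion requires
strict inequality on the inactive side).  A SNP is called **gained** when
strictly more than 85% of windows have delta > 0 *and* EWN(gain) ≥ 5;
**lost** is symmetric.  Zero deltas count in the consistency denominator but
toward neither sign; with 21 windows the consistency bar is therefore 18.
The two calls are mutually exclusive by construction.

Windows running past a chromosome end are dropped (never padded); the
consistency denominator is the surviving count, and a variant with fewer
than half the expected windows surviving is reported as unscannable.  A
reference-allele mismatch with the genome is an error, not an auto-flip,
because silent flips would corrupt the allele orientation that the
population filter established.

At desk scale the scan uses 200 bp windows with stride 8 over ±80 bp — the
same 21-window geometry scaled to the smaller model input (the SNP must lie
inside every window, which caps the span at half the window length).

## Candidate selection

Variants are first oriented so the reference allele is the European-ancestry
(EA) major allele (alleles swapped and both frequencies complemented when
af_ea > 0.5; a record at exactly 0.5 is left unchanged; the operation is
idempotent).  Candidates must be non-coding (no overlap with a user-supplied
coding BED), common (MAF ≥ 5% in EA *or* in the African-ancestry panel),
and in the top 5% by F_ST among the variants passing the first two filters,
keeping boundary ties.  F_ST is Wright's parametric form on panel
frequencies, (H_T − H_S)/H_T with H_T = 2p̄(1−p̄) and
H_S = p₁(1−p₁) + p₂(1−p₂), returning 0 when both panels are fixed for the
same allele; large reference panels make sample-size corrections negligible.
A SNP is AA-dominant when its alternate-allele frequency is higher in AA
than EA.

## Statistical procedures

* **Allelic imbalance.**  At a heterozygous site with total reads ≥ 6, a
  gained call is imbalanced when the alt/ref read ratio exceeds 1.5 *and*
  the one-sided binomial tail P(X ≥ k | n, ½) is ≤ 0.01 (k = alt reads);
  lost mirrors with ref over alt.  The test is one-sided because the
  hypothesis is directional (the direction comes from the EWN call); a zero
  denominator counts as an infinite ratio and the p-value still decides.
* **Fisher comparisons.**  Foreground/background contrasts (imbalance
  fractions, motif hit fractions) use the one-sided Fisher exact test on
  the 2×2 table, testing enrichment of the foreground cell.
* **Bootstrap fraction percentile.**  Where a Fisher test is underpowered,
  an observed fraction is placed within the distribution of fractions from
  `n_boot` without-replacement subsamples of a reference pool (subsampling,
  not resampling, matching the procedure it implements); the returned value
  is the share of subsamples at or above the observed fraction.
* **Fold enrichment.**  log₂(fraction_a / fraction_b); a zero numerator
  yields the −inf sentinel, a zero denominator is an error.

## Motif scanning

PWMs are scored by log₂ odds against a uniform background with a small
pseudocount, log₂((p + pc·bg)/((1+pc)·bg)).  Both strands are scanned at
every offset; minus-strand hits are reported at their forward-strand start.
Per-motif thresholds are calibrated empirically: scan a seeded random
background (≥ 100 kb) and take the smallest threshold whose hit rate is at
most five hits per 10 kb — raising a threshold can only shed hits, so this
is the minimum of a monotone family and the budget always holds on the
calibration background.  Enrichment around eSNPs scans the 100 bp windows
centered on each SNP for *both* alleles (a hit on either allele marks the
SNP hit-positive, avoiding allelic bias), then applies the one-sided Fisher
test per motif against background SNPs.  Per-SNP aggregation is
presence/absence, the simplest reading of occurrence normalized by SNP
count.

## Polygenic risk score

The PRS is intercept + Σ wⱼ·dosageⱼ with weights from a linear probability
model (least squares of 0/1 case status on the dosage matrix).  Dosages are
centered before solving via pseudoinverse, so collinear columns are handled
and constant columns receive weight exactly zero; an optional ridge penalty
is available for p ≈ n settings.  Evaluation partitions control scores at
their empirical q and 1−q quantiles (linear interpolation; q = 0.2 by
default) and reports the fractions of cases strictly above the upper and
strictly below the lower threshold.  `kfold_evaluate` runs seeded stratified
10-fold cross-validation, computing enrichment per fold against that fold's
controls; `transfer_evaluate` trains on one cohort and evaluates repeated
90% subsamples of another.  No covariates are included by default; missing
dosages must be resolved upstream (a mean-imputation helper is provided and
flags what it touched).

## Synthetic data: what it emulates, and what it does not

`synthetic_data` generates every input the pipeline consumes, deterministic
under its seed:

* **Background genome** — i.i.d. bases at 41% GC.  No repeats, no
  composition heterogeneity, no LD.
* **Enhancer training set** — positives are background carrying 1–3
  instances sampled from sharp 12-bp PWMs (60/30/10 weighted toward a
  single instance, since most enhancers are defined by one strong site),
  placed uniformly on either strand.  Negatives are background, except that
  30% carry a one-mismatch "broken" motif instance.  The broken-site
  negatives stand in for the near-motif sequence content of accessible
  chromatin from other tissues — the realistic negative class — and they
  are what forces the learned activity boundary to sit *between* a broken
  and an intact site.  Without them the classifier is mismatch-tolerant,
  tau calibrates below the score of a broken site, and single-base
  gain/loss calls are unattainable in principle; with them the benchmark
  embodies its premise that one substitution can create or destroy a
  functional site.  Default motif sharpness is 0.995 per consensus base for
  the same reason.
* **Variant truth set** — thirds of gain (one-mismatch instance completed
  by the alternate allele), loss (consensus instance broken by it), and
  neutral (background) SNPs, spaced so sliding windows never straddle two
  constructs, with allele frequencies drawn so a configurable fraction is
  AA-dominant and everything arrives EA-major oriented.
* **Het-site read counts** — totals Poisson(depth) truncated ≥ 1, alt reads
  Binomial(total, effect).
* **Cohorts** — a liability-threshold model: individuals are assigned one
  of two populations (dosages binomial in that population's allele
  frequency), liability is the weighted dosage sum plus Gaussian noise, and
  the top liabilities at the requested case fraction become cases.  This
  makes PRS enrichment monotone in effect size by construction.

Passing tests on these data show that the machinery is correct and that the
statistic behaves as designed when its premises hold.  They do not show that
real enhancers are learnable to any particular accuracy, and benchmark
accuracies here (held-out auROC ≈ 0.98) should not be read as claims about
real chromatin data, which carry repeat structure, degenerate motifs,
cooperative binding, and LD that the generator deliberately omits.

## Problem sizes and numerical choices

The default synthetic study trains on 600 positives / 5,000 negatives of
200 bp (doubled by reverse-complement augmentation), calibrates tau on
1,500 fresh negatives, scans 60 planted variants (21 windows each), and
evaluates the PRS on cohorts of 500 + 500 (the acceptance script uses
1,000 + 1,000 for the null run so each fold's control quantile is estimated
from ~100 controls).  One full run takes a few minutes on a single CPU.

Other fixed choices: PWM rows must sum to 1 within 1e-6 (rows off by ≤ 1e-3
in MEME input are renormalized, worse is an error); quantile thresholds use
linear interpolation; EWN boundary convention is score ≥ tau = active;
allele-frequency ties (af_ea = 0.5, af_aa = af_ea) resolve to "no swap" and
"no dominance" respectively; the F_ST top-quantile cut keeps ties; Fisher
tables with an all-zero margin are errors except inside motif enrichment,
where a table with no hit-positive SNP anywhere (or none hit-negative) is
reported as p = 1.

## Known limitations

* The scorer's full-scale profile is untrained out of the box; reproducing
  published real-data numbers (auROC, tau, eSNP counts) requires the
  original ChIP-seq/DHS/1000 Genomes inputs and is out of scope.
* The MEME reader handles the minimal motif format only; the VCF reader is
  a minimal sites-only dialect (biallelic SNVs with AF_EA/AF_AA INFO keys).
* Read extraction from BAM and genotype imputation are upstream concerns;
  allele counts and dosage matrices arrive as TSV.
* The bootstrap percentile and motif-threshold calibration are Monte Carlo
  procedures: their outputs carry seed-dependent noise at the third
  decimal.
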