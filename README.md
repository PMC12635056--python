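# esnpscan

Sequence-based enhancer scoring and sliding-window prioritization of
non-coding SNPs that gain or lose enhancer activity.

Most trait-associated variants are non-coding, and a recurring mechanism is
a single base change that creates or destroys a tissue-specific enhancer.
`esnpscan` is a library + CLI for finding such variants (*eSNPs*): it trains
a convolutional enhancer classifier from sequence, calibrates an activity
threshold tau at a fixed false-positive rate, and scores every candidate
SNP's two alleles across sliding windows, summarizing the effect with the
**essential window number**

> EWN(gain) = #{windows w : score_ref(w) < tau ≤ score_alt(w)},

and symmetrically for loss.  With the default geometry (1 kb windows,
stride 20 bp, centers within ±200 bp of the SNP) there are 21 windows; a
SNP is called a **gained eSNP** when >85% of windows have positive delta
(score_alt − score_ref) and EWN(gain) ≥ 5, a **lost eSNP** symmetrically.

Around that core the package provides the full supporting pipeline:
candidate selection by EA-major allele orientation, minor allele frequency
(MAF ≥ 5% in either population) and top-5% Wright's F_ST; a directional
binomial allelic-imbalance test on heterozygous-site read counts (≥6 reads,
ratio >1.5, p ≤ 0.01); PWM motif scanning with thresholds calibrated to ≤5
false positives per 10 kb of random background and both-allele Fisher
enrichment; and a dosage-based polygenic risk score evaluated by
control-quantile enrichment under 10-fold cross-validation.  A synthetic
data module generates every input with the statistical structure the method
assumes, so the whole pipeline runs and is tested offline.

## Worked example

Simulate a study, train and calibrate the scorer, and scan the planted
variants:

```sh
esnpscan simulate --seed 1 --out work/
esnpscan train --pos work/train_pos.fa --neg work/train_neg.fa \
               --desk-scale --seed 1 --out work/model/
esnpscan calibrate --model work/model/ --neg work/train_neg.fa --fpr 0.01
esnpscan scan --model work/model/ --genome work/genome.fa \
              --variants work/variants.vcf --stride 8 --span 80 \
              --out work/calls.tsv
```

The same run through the library:

```python
import numpy as np
from esnpscan import synthetic_data as sd, enhancer_model as em, ewn_scan

cfg = sd.SimConfig(seed=1)
seqs, labels = sd.simulate_enhancer_dataset(
    cfg.n_pos, cfg.n_neg, cfg.motifs, cfg.seq_len, cfg.seed + 2, gc=cfg.gc)
pos = [s for s, l in zip(seqs, labels) if l == 1]
neg = [s for s, l in zip(seqs, labels) if l == 0]

scorer = em.train(pos, neg, em.ModelConfig.desk_scale(seed=1), seed=1)
print(scorer.metadata["test_auroc"])        # 0.9855700027834109

neg_cal, _ = sd.simulate_enhancer_dataset(
    0, 1500, cfg.motifs, cfg.seq_len, cfg.seed + 10, gc=cfg.gc)
cal = em.calibrate_threshold(scorer, neg_cal, fpr=0.01)
print(round(cal.tau, 3), cal.empirical_fpr)  # 0.282 0.01

genome = sd.simulate_genome(cfg.genome_length, cfg.gc, cfg.seed)
genome, variants, truth = sd.simulate_variants(
    genome, cfg.motifs, cfg.n_variants, cfg.seed + 1)
table = ewn_scan.scan_cohort(
    scorer, cal.tau, {"chr1": genome}, variants, stride=8, span=80)
print(table["call"].value_counts().to_dict())
# {'gained': 20, 'lost': 20, 'none': 20}
```

The held-out auROC (0.9856) says the scorer separates planted-motif
enhancers from background; tau = 0.282 is the smallest score at which at
most 1% of fresh negatives are called active.  The scan recovers all 20
motif-creating variants as `gained` and all 20 motif-destroying variants as
`lost`, while the 20 neutral variants stay `none` — the sliding-window
statistic turns a single-base effect into a robust, direction-consistent
call.  (Numbers are for seed 1; other seeds vary in the third decimal.)

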