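# arraycnv

SNP-array copy-number screening for case/control studies: CNV calling from
LRR/BAF intensity data with a distance-aware hidden Markov model,
arm-scale mosaicism detection from split BAF bands, runs-of-homozygosity
(ROH) analysis, and label-permutation association — together with a
synthetic-cohort generator that plants ground-truth events so every stage
of the pipeline can be verified end to end.

It is aimed at statistical geneticists analysing array genotyping
intensity data (the PennCNV/PLINK style of workflow) who want a tested,
scriptable Python implementation of that workflow, and at methodologists
who need a simulator with known truth to benchmark CNV and mosaicism
callers.

## The model

**Signal.** At marker *i* the array reports the Log R Ratio
LRR_i = log2(R_obs / R_exp), a proxy for total copy number, and the
B-allele frequency BAF_i, which clusters at 0, 1/2, 1 under diploidy.
A deletion depresses LRR and removes the heterozygous BAF band; a
duplication raises LRR and splits the band to 1/3, 2/3.

**CNV HMM.** Hidden states {CN0, CN1, CN2, CN2-LOH, CN3, CN4}. Emissions
are the product of a Gaussian on LRR (state mean/SD) and a BAF mixture
whose cluster weights follow Hardy–Weinberg proportions at the marker's
population B-allele frequency (PFB), adapted to the state's allele count,
plus a uniform outlier component. Transitions decay with inter-marker
distance *d*: the off-diagonal i→j probability is
π_j · ρ_max (1 − e^(−d/D)), so adjacent markers resist switching.
Each non-diploid Viterbi segment is scored by an emission-only log10 Bayes
factor against CN2; calls need confidence ≥ 10 and ≥ 15 probes (≥ 3 for
homozygous deletions), same-copy-number neighbours merge when their gap is
< 20 % of the smaller call, and calls spanning a centromere are split at
the flanking probes.

**Before the HMM**, per-sample QC excludes noisy arrays (LRR SD within
[−2, 2] and het-band BAF SD within [0.15, 0.85] beyond the cohort
mean + 3 SD; call rate ≤ 95 %), and LRR is corrected by regressing out the
top principal components of a stable-probe intensity matrix followed by a
per-sample GC-wave adjustment.

**Mosaicism.** An event in a fraction *f* of cells splits the het band to
0.5 ± d. Arms are screened on the SD/IQR of het-band BAF (robust
median + 5·MAD outlier rule), breakpoints mapped by a two-state HMM on
|BAF − 0.5|, and the cell fraction recovered as f = 4d/(1+2d) for losses,
4d/(1−2d) for gains.

**ROH.** Runs must satisfy five criteria simultaneously: ≥ 1 Mb, ≥ 100
SNPs, ≥ 1 SNP / 50 kb, ≤ 1 heterozygote per Mb, no gap > 1 Mb. A region
scan reports loci where ≥ 10 cases carry overlapping runs (extended while
≥ 7 cases remain and no new control appears) and ≥ 7-case / 0-control
loci.

**Inference** is empirical throughout: case/control labels are permuted
with group sizes preserved; p = (r+1)/(n+1) pointwise (EMP1) and a
max-statistic family-wise p (EMP2) for the per-locus segmental scan.

## Worked example

`examples/03_call_cnvs.py` plants a 1 Mb heterozygous deletion and a
1.5 Mb duplication in one simulated sample and calls them:

```
case_0001  chr1:10,078,889-10,984,633  CN1  46 probes  conf 125.0  906 kb (0.9 Mb)
case_0001  chr1:40,006,158-41,480,223  CN3  78 probes  conf 108.5  1474 kb (1.5 Mb)
```

Both planted events are recovered at their outermost probes; `conf` is the
log10 Bayes factor versus diploidy (the filter threshold is 10), and the
sizes follow the 1-based inclusive convention (end − start + 1).

`examples/04_mosaic_screen.py` plants a mosaic loss in ~18 % of cells over
most of 15q and recovers it from the BAF split alone:

```
1 outlier arm(s) among 60 sample-arms
case_0001  chr15:44,139,310-95,983,445  d = 0.052  direction = loss  cell fraction ~= 0.19 (planted 0.18)
```

The other examples cover simulation (`01`), QC and intensity correction
(`02`), ROH calling and the case-enriched region scan (`05`), and burden /
permutation association with known-locus annotation (`06`). A thin CLI
(`arraycnv simulate|qc|correct|call-cnv|mosaic|roh|assoc|annotate`) wraps
the same functions for shell use.

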