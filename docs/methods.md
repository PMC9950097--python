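# Methods

This note documents the models, the parameter choices and their
rationale, what the simulator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Signal model and simulator

The generator produces, per sample, aligned vectors of LRR, BAF and
genotype over a marker map. Genotypes are drawn from Hardy–Weinberg
proportions at each marker's population B-allele frequency (PFB, drawn
Beta(0.5, 0.5) truncated to [0.01, 0.99] — a U-shape typical of genotyping
arrays). BAF is the genotype cluster mean (b/2 for b copies of the B
allele) plus Gaussian cluster noise; with probability `outlier_rate` a
value is replaced by Uniform(0, 1), modelling genotyping failures. LRR is
Gaussian around a per-copy-number state mean.

Defaults (all exposed on `NoiseModel` and `HmmParams`):

| parameter | default | rationale |
|---|---|---|
| LRR state means CN0..CN4 | −3.0, −0.66, 0, +0.40, +0.68 | conventional Illumina/PennCNV-scale values; log2(k/2) compressed by array saturation |
| `lrr_sd` | 0.18 | typical per-probe noise of a passing array sample |
| `baf_sd` | 0.03 | typical BAF cluster width |
| `outlier_rate` | 0.005 | sub-percent assay failure rate |
| `gc_wave_amplitude`, `batch_shift_sd` | 0 (benchmarks use 0.3 / 0.1) | artifact magnitudes are study-specific; the recovery benchmark turns them on to exercise the correction |

Planted events override the diploid draw: deletions/duplications redraw
LRR at the state mean and BAF at the allele-count clusters (CN0 BAF is
uniform — no signal); ROH events force homozygous genotypes at PFB;
mosaic events shift heterozygous BAF to 0.5 ± d and LRR by
log2((2 + c·f)/2) for a signed single-copy change c at cell fraction f,
with d = f/(4−2f) (loss), f/(4+2f) (gain), f/2 (copy-neutral LOH).

What the simulator does **not** emulate: raw two-channel probe
intensities (LRR/BAF are generated directly; `compute_lrr_baf` is
exercised on its own constructed cluster fixtures), linkage
disequilibrium between markers, family structure, position-autocorrelated
noise beyond the smooth GC field, and chemistry-specific cluster
distortions. Passing recovery tests therefore demonstrate correctness of
the algorithms under the stated signal model, not calibrated performance
on any particular array product.

## Sample and marker QC

Per-sample noise metrics restrict LRR to [−2, +2] (excluding real
copy-number signal) and BAF to the heterozygous band [0.15, 0.85]. The
exclusion rule is cohort-level: a sample fails when its metric exceeds the
cohort mean + 3 cohort SDs — read as an outlier-sample screen, computed in
a single pass (an iterate flag exists but is off by default, since the
screen's purpose is to remove gross outliers, not to converge).

The Hardy–Weinberg test is the exact conditional test (no mid-p),
implemented with the stable ratio recurrence over heterozygote counts and
verified against full enumeration. Sex-differential missingness uses
Fisher's exact test; sex-differential allele frequency uses the
allele-count chi-square with a Fisher fallback when an expected cell is
below 5. Relatedness is the method-of-moments IBD decomposition of IBS
counts (PI_HAT = P(IBD=2) + P(IBD=1)/2, probabilities truncated to [0, 1]
and renormalised). LD pruning follows the sliding-window greedy rule
(window 50 SNPs, step 5), removing the later marker of a pair above the
r² threshold; presets 0.2 (ancestry PCA prep) and 0.3 (ROH prep).

## Intensity correction

Order: principal-component regression, then GC adjustment, then
per-sample median re-centring.

The PCA is fitted on stable probes (flagged uniquely-mapping and below
the 90th cross-sample variance percentile, which drops common-CNV
probes). Both the PCA and the per-probe regressions use a robustified
matrix in which any value deviating from its probe's cross-sample median
by more than 0.3 is replaced by that median. This matters: with tens of
samples, the sample-specific direction of a rare deletion is otherwise
picked up by noise components and partially regressed away; artifact
structure (quantity/quality, batch, waves) lives well inside ±0.3 and is
retained. The fitted artifact is subtracted from the *raw* values, so CNV
signal passes through unattenuated.

GC adjustment is per sample (each sample has its own wave phase): a
linear fit (spline optional via `degree`) of LRR on local GC over markers
with |LRR| < 0.5, so CNV probes do not enter the fit. The final
median re-centring removes residual whole-sample offsets; the genome-wide
median is copy-neutral in any realistic sample.

## CNV HMM

Six states with CN2 as reference; CN2-LOH stays in the state space (it
sharpens boundaries between deletions and autozygous tracts) but is
excluded from CNV output and routed to ROH context. BAF cluster densities
are truncated Gaussians on [0, 1] with the truncated tail mass assigned
to the boundary points, so BAF values clipped at 0/1 are handled
consistently across states; every state mixes in a 1 % uniform outlier
component.

Transition matrices use ρ(d) = ρ_max(1 − e^(−d/D)) with D = 100 kb and
ρ_max = 0.9; ρ(0) = 0 makes coincident markers inseparable, and in the
long-distance limit rows approach the state priors. Priors put 0.99 mass
on CN2.

The Bayes factor is defined as the emission-only log10 likelihood ratio
of the called state versus CN2 summed over the segment's probes — the
upstream tools leave the statistic unstated, and the emission-only form
makes confidence additive in segment length and independent of the
transition parameters. Confidence and probe counts are recomputed after
merging and after centromere splitting. Merging measures the gap
boundary-probe to boundary-probe (next.start − prev.end − 1) and uses a
strict `<` at the 20 % threshold; ties do not merge. The pipeline order is
merge → split → filter, which is idempotent (re-merging split halves and
re-splitting them returns the same calls). Sex chromosomes are excluded
from CNV calling; the sex-aneuploidy screen covers them.

## Mosaic screen

Arm statistics use only BAF in (0.15, 0.85); arms with fewer than 50 such
markers are reported but never flagged (they are whole-arm ROH, a
distinct cloud). The outlier rule is median + 5·MAD (normal-consistent
MAD) on either SD or IQR — a numeric stand-in for what is otherwise a
visual scatter-plot judgement; k = 5 keeps the null false-positive rate
well under 1 %.

The breakpoint HMM works on y = |BAF − 0.5| of het-band markers: state N
emits half-normal(0, σ), state M a folded normal at deviation d, both
mixed with a uniform outlier component (weight 0.02) so genotyping
failures cannot anchor either state. d is profiled over a grid
(0.02–0.30, step 0.01) by Viterbi likelihood. σ is estimated from the
cohort's non-outlier arms via the median IQR/1.349 (IQR-based, so BAF
outliers inside the band do not inflate it). Because the Viterbi
transition cost systematically trims weak-signal boundaries, each
boundary is refined afterwards by an emission-only cumulative-sum
changepoint within an 80-marker window. Events shorter than 25 het
markers are discarded. Direction comes from mean LRR over the event with
a ±0.02 dead zone mapping to "unknown" (copy-neutral events shift BAF but
not LRR); the reported d is the mean |BAF − 0.5| over the event.

## ROH

The five run criteria are implemented directly from their textual
definitions rather than by emulating PLINK's sliding-window internals;
the het constraint is a running budget of max(1, ⌊span/Mb⌋)
heterozygotes. Missing genotypes are neutral: they neither break a run
nor count as heterozygous (a flag treats them as breaks). Runs grow
greedily; after an emitted (maximal) run the scan resumes past its break
point, and after a failed run it resumes just past the run's first
heterozygote so cleaner windows starting inside are not missed. An
independent checker revalidates every emitted segment from the genotypes
in the test suite.

In the region scan, "a new control appears" is interpreted as the
control-carrier count exceeding its maximum over the seed region.
Regions found by the ≥ 7-case/0-control rule that lie entirely inside a
seed-extension region are not repeated. Reported boundaries are
pruned-marker positions.

## Permutation inference

All tests permute case/control labels with group sizes preserved and use
the add-one estimator p = (1 + r)/(1 + n), which can never return zero.
Mean-size contrasts use a ratio-of-sums statistic (group total kb / group
event count) so samples without events are handled naturally; a group
with zero events contributes zero. The segmental scan's statistic at each
marker is case carriers − (n_case/n_control)·control carriers; EMP2 is
the fraction of permutations whose genome-wide maximum statistic reaches
the marker's observed value, the standard max-statistic family-wise
correction. Permutations are processed in chunks to bound memory.

For discrete statistics (carrier counts, event rates) the one-sided
empirical p of a null contrast sits at or above 0.5 because of tie mass
at zero — expected behaviour, asserted as such in the tests.

## Problem sizes and determinism

The recovery benchmarks run 60 samples on a ~3,000-marker, one-chromosome
map (≈ 85 planted events), the permutation-calibration checks use 1,000
scaled replicates of 200–1,000 permutations, and the power check uses 60
replicates at the full 136/97 sample sizes with 500 permutations each —
sizes chosen so the whole suite and the reproduction script each finish
in well under a minute while keeping Monte-Carlo error small relative to
the margins being tested. Every stochastic component takes an explicit
seed; identical seeds give byte-identical simulated files.

## Known limitations

- HMM parameters are fixed and configurable, not EM-trained per cohort.
- No trio/de-novo calling, no sex-chromosome CNV calling, no phasing or
  haplotype-aware mosaic detection.
- The known-locus annotation ships a small hg19 table of recurrent
  schizophrenia-associated loci; gene-level reporting needs a user-supplied
  gene BED.
- Breakpoint precision for low-grade mosaicism (d ≈ 0.05) is limited by
  the per-marker information content to roughly 1–2 % of an arm's length;
  the changepoint refinement removes bias but not variance.
- Printed rates in cohort summaries follow the definitions
  (events/samples); they are not calibrated against any external dataset.
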