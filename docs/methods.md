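# Methods

`hapbsa` implements bulked-segregant analysis (BSA) QTL mapping for
haplodiploid experimental-evolution designs, together with a forward
simulator of the whole experiment that supplies every input with known
ground truth. This note records the models, the parameters that matter, the
numerical conventions, and the design choices made where the design was
genuinely open.

## The experimental design being modelled

A highly inbred, homozygous "mother" strain is crossed to a **single haploid
male** drawn from a genetically heterogeneous resistant strain. Because
males in arrhenotokous species are haploid, the sire contributes exactly one
allele per site, so every F1 female carries one maternal and one paternal
haplotype and the entire segregating population is a two-haplotype system at
the informative sites (those where the sire's allele differs from the
mother's). The segregating population is expanded and split into 11 pairs of
sister populations of ~650 census females; one member of each pair is
propagated under pesticide selection, the other untreated, for ~35
generations. Each population is then sequenced as a pool (up to 1,000
females; the whole population when smaller), and one RNA library per
population is sequenced as well.

## Forward simulator

**Genome and markers.** The toy genome is three chromosomes of 7.5/5/2.5 Mb
(ordered by decreasing length, as in the analysis layout), with candidate
marker sites placed uniformly at 2 per kb. At each marker the resistant
strain is heterozygous with probability 0.5 or else homozygous for the
non-maternal allele; the sire receives one allele per site (a fair draw at
heterozygous sites). Genomes are tracked as 0/1 arrays over the informative
sites, 1 denoting the transmitted resistant-parent allele.

**Transmission.** Standard arrhenotoky: a daughter receives a recombinant
maternal gamete plus the haplotype of a random father; a son receives a
recombinant maternal gamete only. Meiosis places exactly one obligate
crossover per chromosome at a uniform bp position with independent
assortment across chromosomes — each chromosome is 50 cM regardless of
physical length, which keeps realistic linkage blocks at toy scale. The
male census defaults to one third of the female census (a female-biased sex
ratio typical of spider mites); males matter only as fathers and through
their contribution to drift.

**Selection.** Each causal locus carries a selection coefficient `s` and
dominance `h` of the resistance allele. Offspring viability in the selected
treatment is multiplicative over loci: females survive with probability
1−s (no resistant allele), 1−s(1−h) (one copy), 1 (two copies); haploid
males with 1−s or 1. Survivors are resampled to the census sizes. The
defaults are s = 0.2 and h = 0.1 per locus at three loci (two on chromosome
1, one on chromosome 2). The modest per-generation `s` is deliberate: the
emulated protocol escalated doses gradually, so sweeps completed near the
end of the ~35 generations. Fast sweeps (s ≥ 0.6) fix in under ten
generations and leave megabase-scale ragged hitchhiking shoulders that
occupy a large fraction of the toy genome in genetic terms; under the
circular-rotation null (below) those shoulders inflate the threshold into
their own plateau and fragment QTL runs. The slow-sweep regime is both more
faithful to the protocol and gives clean, reproducible three-QTL recovery.

**Burn-in.** Eight neutral generations separate the cross from the onset of
selection, collapsing the population expansion (~3–4 generations), the
additional pre-selection propagation of each pair, and the effectively
neutral early low doses. Pairs are founded from a common bootstrap sample
of the burn-in population; both members start identical and evolve
independently.

**Sequencing emission.** Pooled DNA: per-site depth ~ Poisson(80 by
default), alternative reads ~ Binomial(depth, read-level allele frequency).
Inside the copy-number-variable (CNV) region the resistant haplotype carries
extra template copies, so both the local depth and the read-level allele
frequency are biased accordingly (frequency f becomes f·c / (1 + f(c−1)) at
c copies). Per-gene DNA coverage and RNA counts are negative-binomial with
dispersion 0.01 (~10% CV per gene, typical of deep pooled libraries).
RNA means scale with a cis-regulatory fold multiplier raised to the mean
resistant-haplotype dose (so a pool fixed for the resistant haplotype shows
the full fold change and a 50:50 pool the geometric midpoint) and with local
copy number; RNA reads at exonic sites are allele-specific, the
overexpressed haplotype contributing proportionally more reads.

**Default architecture.** The CNV region spans chr2:2,492,001–2,505,200
(13.2 kb, exactly five of the tiled 2 kb gene models, three copies on the
resistant haplotype) and coincides with the third causal locus, mimicking an
amplified detoxification-cofactor locus; cis-eQTL defaults place a 5× gene
at the first causal locus and a 2× gene at the second, while the third
locus's expression effect arises purely from dosage (~3×).

**qPCR.** Ct = ct0 − log_E(template × copies) + Normal(0, sd) in duplicate,
with per-cycle efficiency E ∈ (1, 2].

**Bioassays.** Deaths ~ Binomial(n, Σ_class proportion × Φ(slope·(log10
dose − log10 LC50_class))) over a mixture of genotype classes. Default
LC50s: susceptible 5 mg/L, resistant 2,000 mg/L, F1 placed at a degree of
dominance of −0.6 (incompletely recessive).

**Randomness.** Every draw flows from the single global seed through named
substreams (`hapbsa._rng.substream`), so identical configuration and seed
reproduce every emitted file byte for byte.

## Site inference and filtering

At strain-heterozygous sites the transmitted allele is inferred from the
offspring pools: the non-maternal allele is accepted when it exceeds a 5%
frequency floor in at least one pool (the floor guards against
sequencing-error alleles and is configurable; the choice of floor is ours).
Sites where the mother is not homozygous are flagged `low_quality` and never
used silently. A site is non-segregating *for a pair* when the same allele
is at frequency ≥ 0.95 in both the selected and the control member (the
boundary value is dropped; either allele fixed drops the site), and excluded
globally only when every pair drops it.

## Windowed scans

The DNA scan averages transmitted-allele frequencies in 75 kb windows
advanced in 5 kb steps; windows start at position 1 (the grid origin is
configurable), trailing partial windows are dropped so the ≥38-site
criterion is comparable genome-wide, and windows with fewer than 38 sites
are missing. Per pair the control window value is subtracted from the
selected one; the replicate average ignores missing pairs rather than
propagating missingness. The RNA scan uses exonic biallelic positions with
coverage ≥ 20 in both members and control major allele frequency < 0.95,
takes absolute per-pair frequency differences, and averages them in 500 kb
non-overlapping windows. Windows are 1-based inclusive internally and
exported as 0-based half-open BED.

## Significance by circular permutation

The per-pair windowed difference profiles are concatenated chromosome by
chromosome into a ring (the end of the last chromosome joined to the start
of the first) to preserve linkage across the seam. Each of the 10^4 (by
default) permutations rotates every pair's ring by an independent uniform
window offset, averages the rotated rings, and records the maximal absolute
deviation. The observed averaged track is thresholded at the empirical
upper 0.05 quantile of this max-deviation distribution — the value exceeded
by exactly ⌊0.05·n⌋ permutation maxima. The construction is genome-wide
(family-wise) even though the level is conventionally labelled an FDR; the
output keeps the conventional label. Windows missing in any pair are
removed from the rings before rotation, with their linear positions
remembered (no imputation). Rotation resolution is the window and offsets
are independent across pairs; the alternative conventions (site-resolution
rotation, shared offsets) are not exposed.

Significant windows (|mean| ≥ threshold) form maximal contiguous runs — one
QTL call each; runs never span chromosome boundaries, are not merged across
gaps, and peak ties break leftmost, all for determinism. Each call is
extended into a QTL interval by walking outward from the peak: extension
continues while the most recent block of five consecutive windows contains
at least one window within 0.005 of the peak value, and the interval spans
the outermost peak-similar windows reached. The top-2 sub-threshold local
maxima are reported as subsidiary peaks, without significance claims.

## CNV, qPCR and dosage

Count matrices are normalized with median-of-ratios size factors (the
reference is the per-gene geometric mean over samples, computed over genes
with no zero count; factors are medians of count/reference). The
normalization is re-implemented here rather than delegated because the
pipeline needs it for DNA coverage matrices as well as RNA. Relative
coverage divides normalized counts by the mean of the single-copy baseline
samples (the control populations by default; the susceptible parent is an
alternative baseline choice the data do not disambiguate). CNV calling is
gene-resolution: maximal runs of consecutive genes at relative coverage
≥ 1.5 (separating one from two copies at moderate noise; configurable)
become segments, with the copy estimate the rounded mean over member genes
(floor 1) and the raw mean retained.

qPCR copy number uses efficiency-corrected relative quantification:

    CN_s = E_t^(Ct_t,cal − Ct_t,s) / E_r^(Ct_r,cal − Ct_r,s)

with replicate Cts averaged before exponentiation, the calibrator sample
defined as copy number 1, and a single-copy reference amplicon. Composed
with the simulator's noiseless Ct emission this is exactly the identity on
true copy number, for any efficiency.

Expression fold change is the ratio of group means of normalized counts
(zero-denominator genes reported missing). Differential-expression *calls*
are consumed, not produced: a provided DE table is cut at |FC| ≥ 2 and
adjusted p ≤ 0.05, and a DEG lies within a QTL interval when its span
overlaps it by ≥ 1 bp.

## Mode of inheritance

Dose-response data are fitted by maximum-likelihood binomial regression with
a probit link on log10 concentration (base-10 logs throughout, the probit
convention); LC50 = 10^(−α/β) with a delta-method 95% CI. Complete
separation (0% or 100% kill everywhere) is rejected rather than fitted.
Abbott's control-mortality correction is available but off by default.
Stone's degree of dominance D = (2·logLC50_F1 − logLC50_R − logLC50_S) /
(logLC50_R − logLC50_S) is clipped to [−1, 1] with a flag. The
monogenic-recessive test compares backcross kill to c = 0.5·W(F1) +
0.5·W(R) per dose with a χ² over the dead/alive cells of every dose;
df = number of doses, since no parameter is estimated from the backcross
data (the df convention is ours); doses with degenerate expectation (c of
exactly 0 or 1) are excluded with a warning. A maternal effect is flagged
when the reciprocal F1 LC50 CIs are disjoint.

## What the simulator does and does not emulate

It reproduces the features the pipeline is sensitive to: two-haplotype
segregation from a haploid sire, linkage under one obligate crossover per
chromosome, drift at realistic census sizes, slow multi-locus sweeps,
read-sampling noise at realistic depths, CNV-driven coverage and
allele-frequency biases, cis-regulatory and dosage effects on RNA, qPCR
chemistry, and probit mortality. It does not emulate sequence-level reads
(no mapping error, indels, base qualities), multi-allelic sites, sex-ratio
dynamics, dose-escalation schedules (a constant modest `s` stands in),
fitness costs of resistance in the controls, or gene-length/GC biases in
counts. Passing tests therefore validate the analysis logic and its
calibration under the modelled noise sources, not robustness to alignment
or library-preparation artefacts.

## Problem sizes used in validation

The three-QTL recovery scenario runs the default genome (15 Mb, ~30,000
markers, 22 populations, 43 generations including burn-in) with 1,000
rotations. The drift calibration runs 200 independent no-selection
experiments on a reduced 2 Mb genome at 1 marker per kb, pooled depth 60,
and 500 rotations each, with every experiment deriving its own threshold;
these sizes keep the full validation within a desk-scale run while leaving
the per-experiment census, pair count, and generation count at the design
values. The DNA/RNA scan-concordance check uses the default genome with a
per-site RNA depth of 100× so that the RNA scan's absolute-difference noise
floor (≈ √(1/2·depth)) sits below the drift signal it must rank.

## Known limitations

* The permutation threshold inherits the signal-in-null conservatism of
  rotation tests: strong, broad sweeps inflate the null maxima, and on a
  small toy genome this compresses the margin between peaks and threshold.
* Run-based QTL calling can fragment a single broad signal if the track
  wiggles around the threshold; runs are deliberately not merged.
* CNV calling is gene-resolution and will not find amplifications smaller
  than a gene model or estimate breakpoints.
* The monogenic χ² treats parental response tables as exact; with small
  parental samples the test is anti-conservative.
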