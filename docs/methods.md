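# Methods

## Overview

`valkit` couples a synthetic tumor copy-number generator to a scar-based HRD
classifier and the full set of analytical-validation estimators used to
qualify a diagnostic biomarker (limit of blank, limit of detection,
concordance, precision, interfering substances). Nothing in the package
touches real sequencing data: the generator plants a known HRD contrast and
known study conditions, and the validation machinery must recover them.

## The genome and profile model

The default genome is 22 chromosomes of 100 Mb with the centromere at 40%
(44 arms, 2.2 Gb). Coordinates are 0-based half-open internally; the TSV
and SEG exports are 1-based inclusive. Real-build coordinates can be passed
through the same config, but none are bundled.

A profile is an ordered list of allele-specific integer segments
(total copy number t, minor copy number m ≤ t − m) that tile each arm
exactly, with no two adjacent same-arm segments in the same state (maximal
segmentation).

### Planting the HRD contrast

Per arm, breakpoints are Poisson with rate `breakpoint_rate_{pos,neg}` per
100 Mb (defaults 10 vs 1.5). In positive genomes each breakpoint spawns,
with probability `short_segment_bias_pos` = 0.5, a companion breakpoint
0.3–8 Mb downstream (short-segment excess). Oscillation bursts (positives
only, Poisson mean 6 per genome) carve an alternating run of 5–11 short
(0.2–2 Mb) segments between states t and t+1 into a host segment; the burst
is forced to odd length so both flanks keep the host state and the full
alternating chain includes them. Segment states are drawn with weights
favoring the diploid state; LOH status (m = 0) is decided first with
probability `loh_fraction_{pos,neg}` (0.35 vs 0.05) so the genome LOH
fraction tracks the target directly.

### VAFs and purity

Heterozygous SNPs are placed uniformly at `snp_density` = 1 per Mb
(~2,200 genome-wide). A SNP reports the allele on the minor or major
haplotype with equal probability; its expected VAF at purity ρ in segment
(t, m) is `(ρ·c + (1−ρ)) / (ρ·t + 2(1−ρ))` with c the allele's copy
number, sampled binomially at Poisson(`depth` = 500) reads. At ρ = 0 every
het SNP is centered at 1/2; at ρ = 1 it reports c/t.

### What a replicate observes

The production pipeline's segmentation model is not public, so segmentation
error is not emulated; instead each replicate re-decodes integer copy
numbers from purity-attenuated signals. Per segment the implied log-ratio
`log2((ρt + 2(1−ρ))/2)` and allele imbalance `ρ(t/2 − m)/(ρt + 2(1−ρ))`
are perturbed with Gaussian noise (`noise_sd` = 0.02 and half of it) and
inverted with ρ known. Decoding error therefore scales like `noise_sd/ρ`:
near-perfect above ~15% purity, increasingly scrambled below ~8%, and a
flat diploid profile below 2% (tumor signal unresolvable). This one dial
gives the LoD study its dose–response without read-level simulation. The
segment-level noise stands in for the per-probe noise of a real pipeline
after within-segment averaging, which is why it is small.

### Dilution, QC and interferents

Mixing specimen DNA (purity ρ) at mass fraction d with matched normal gives
effective purity d·ρ (standard mass balance); VAFs are regenerated at the
same SNP positions and the profile re-decoded at the effective purity. QC
failure is two independent Bernoulli gates — library construction then
hybrid capture — with per-study default rates chosen to match the published
failure counts (precision: 0.005/0.010 ≈ 4 LC + 8 HC in 792; LoD: 0/0.053 ≈
15 HC in 282; LoB and interference: 0, as all their replicates passed).
All nine configured interferents default to a null effect, matching the
observed 100% concordance in spiked samples; depth-deflation and
noise-inflation hooks exist for robustness experiments.

### Study designs

Cohort generators default to the published shapes: LoB 5 blank specimens ×
12 replicates; LoD 3 positive specimens × 5 dilution levels (19/19/19/19/18
replicates ≈ 282), with levels 0.2–0.4 interpreted as *target purities*
(the published adjusted purity at the 0.2 level is ~23%, i.e. the level is
the resulting purity, not the mass fraction — the generator converts to
d = level/ρ); precision 22 specimens × 36 replicates in the two-group
factorial (3 sites × {3 lots × 2 sequencers | 2 lots × 3 runs} × 2
replicates = 792); concordance 101 reversion-positive + 130 HRR-wildtype
specimens; interference per-substance plans totalling 112 substance-sample
replicates plus 6 two-replicate necrosis samples. LoB specimens are flat
diploid genomes at purity 1.0, so their negative calls come from the
classifier rather than from the low-purity gate.

## Features

107 named features in a fixed schema: for each of three regions (whole arm,
telomeric 20%, centromeric 20% of each arm — the extents are configurable,
as no standard fraction exists) the per-arm breakpoint summaries (total,
mean, max, arms ≥ k for k ∈ {1,2,3,5,8,10}), the segment-size spectrum
(counts and length fractions in bins <1/1–3/3–10/10–30/30–100/≥100 Mb plus
log10-size moments, clipped to the region window), and oscillation-chain
summaries (counts of maximal alternating-two-state runs ≥3/≥5/≥10, segments
in chains, longest chain); plus the per-chromosome longest chain (22) and
gLOH. A breakpoint is any change in the allele-specific (t, m) pair —
copy-neutral LOH boundaries are scars — with a total-CN-only variant
exposed. Oscillation chains need ≥ 3 segments and are judged on total CN
only. gLOH merges adjacent m = 0 segments into runs and excludes runs
covering ≥ 90% of an arm (whole-arm events are not HRD scars); the
denominator is the full genome.

## Classifier

XGBoost with desk-scale defaults (200 trees, depth 3, learning rate 0.1,
single-threaded histogram method for determinism); the production model's
hyperparameters and feature list are unpublished, so this schema is a
documented public stand-in spanning the same feature families. Cohorts are
split 7:3 stratified by label. The score is the raw ensemble probability
(no monotone calibration). The positivity cutoff ships as the conventional
0.7 with ≥ treated as positive (the tie rule is configurable); an optional
calibration picks the largest threshold keeping ≥90% sensitivity on held-out
positives. Calls are three-state: QC failure → unknown (no score), effective
purity < 10% → unknown (low purity), else positive iff score ≥ cutoff.

## Validation statistics

All proportions use the two-sided Wilson score interval with the exact
normal quantile and no continuity correction — this reproduces every
published interval digit-for-digit (the shipped
`data/printed_counts.tsv` fixture and `verify_printed_tables` check all of
them at printed precision). One documented exception: for 112/112 agreeing
interference replicates Wilson gives a 96.68% lower bound and the exact
Clopper–Pearson method 96.76%, neither matching the reported 96.88%; that
interval's method is unidentifiable and it is excluded from reproduction.

The dilution factor is this package's concrete choice for an unspecified
quantity: the ratio `mean(|VAF_diluted − ½|) / mean(|VAF_undiluted − ½|)`
over shared het SNPs that are allele-imbalanced in the undiluted specimen
(|VAF − ½| above 0.02 and above four binomial standard errors, so balanced
SNPs whose deviation is pure noise stay out of the set), clamped to [0, 1]
and requiring ≥ 50 usable SNPs. It recovers a planted mass fraction to
within ±0.03 at depth 500 with ~2,200 SNPs. Adjusted tumor purity is the
undiluted computational purity times this factor; per-specimen LoD is the
mean adjusted purity at the lowest dilution level with hit rate ≥ 95%, and
the overall LoD is the median across specimens.

Reproducibility and repeatability exclude QC-invalid and unknown-status
replicates from numerator and denominator alike; repeatability pairs are
keyed by (specimen, site, lot, sequencer/run, plate) and require both
members valid. The majority-call reference is positive at exactly 50%
(verbatim rule). Interference references come from each specimen's
normal/vehicle control replicates; specimens with no control (necrosis) are
reported at sample level against their own majority but excluded from the
overall aggregate. Report percentages are rounded half-up to two decimals.

## Problem sizes and determinism

Default end-to-end runs use reduced cohorts (LoD 6 replicates per level,
precision 6 specimens × 36 replicates, concordance 25+30; training 60+60
specimens), with `published_scale=True` restoring the published sizes. The
precision reduction keeps the full 36-replicate factorial per specimen and
reduces the specimen count instead, preserving the repeatability pairing
structure. Every stage seeds `numpy.random.default_rng` from per-stage
seeds derived from one master seed; reruns are byte-identical, and
`scripts/acceptance.py` threads its `--seed` through every stochastic
stage.

## What passing tests do and do not show

The generator plants clean, strongly separated scar patterns with fixed
truth labels: holdout AUC ≈ 1 and near-perfect synthetic PPA/NPA say the
pipeline recovers what was planted, not that the classifier would achieve
the published concordance on FFPE specimens. Real tumor data add
segmentation error, subclonality, FFPE artifacts, purity estimation error
and imperfect truth labels, none of which are modeled. The count-derived
statistics, by contrast, are exact arithmetic on the published counts and
are reproduced digit-for-digit. Known limitations: no read-level
simulation; no FFPE chemistry; the feature schema is a public stand-in for
an undisclosed production list; dilution levels for LoD assume the
level-as-target-purity reading described above.
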