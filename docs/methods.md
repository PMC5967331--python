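# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic test bed does and does not establish.

## Somatic filtering

Filtering operates on per-sample allele-count tables (chrom, pos, ref,
alt, depth, alt reads, PHRED-scaled variant quality, functional class,
population allele frequency); alignment and primary variant calling are
upstream of the package by design.

Quality gate: in-bait ∧ depth ≥ `min_depth` (10) ∧ alt reads ≥
`min_alt_calls` (5) ∧ QPHRED ≥ 20 for SNVs / 30 for indels. Somatic
status per tumor: VAF ≥ `vaf_somatic_tumor` (0.15) in the tumor ∧ VAF <
`vaf_max_remission` (0.05) in remission. Cross-tumor rescue: a one-tumor
somatic call becomes shared when the other tumor shows VAF ≥ `rescue_vaf`
(0.05) **or** ≥ `rescue_min_reads` (2) alt reads — clonality or coverage
differences can hide a truly shared mutation in one sample. Population
exclusion: population MAF > `pop_af_max` (0.01) removes the call; a
*missing* frequency keeps it, since absent database evidence must not
delete a candidate.

Boundary semantics are deliberately mixed (≥ 0.15 but < 0.05, > 1%) and
are pinned by a golden test enumerating all of them. "≥ 5 variant calls"
is read as alt-supporting reads from a single pool (not per-strand).
Duplicate site keys within one sample are rejected at parse time rather
than silently merged. A remission row with zero depth makes the somatic
test unassessable (undetermined), not somatic: a `< 0.05` comparison
against an undefined VAF must not promote a call.

Without a remission sample (pairs-only patients) diagnosis-side somatic
status cannot be established; such candidates are reported as
undetermined and only relapse-acquired events — present at relapse with
no rescue-level evidence at diagnosis — are classified.

## Cancer cell fraction

CCF = VAF·(α·n_t + 2(1−α))/(α·m), assuming normal cells diploid at every
autosomal locus (configurable to 1 copy for male sex chromosomes).
Multiplicity m is the integer in [1, n_t − n_minor] whose expected VAF is
nearest the observed one — deterministic and testable against brute-force
enumeration. The 95% interval is exact Clopper–Pearson on the alt-read
count mapped through the (monotone in VAF) CCF transform, truncated to
[0, 1.5]; the point estimate is truncated to [0, 1] with the raw value
retained. Exact intervals were chosen over normal approximations for
correct coverage at the depths involved (~91×); measured coverage on the
simulation grid is ≈ 0.95–0.97, slightly conservative as expected for
Clopper–Pearson. Subclonality: CI upper bound < 0.95. Mutations falling
in fitted homozygous deletions are flagged inconsistent instead of being
assigned a CCF. In the pipeline, purity comes from the copy-number fit
(overridable per sample); sites outside any segment default to (2,1).

## Copy number

Signals are exome-derived: LRR = log2(tumor depth / normal depth) per
germline SNP, median-centred; BAF = tumor B-allele fraction at SNPs
heterozygous in the normal sample (normal BAF in [0.25, 0.75] at ≥ 10×).
Phase is discarded (mirrored deviation |BAF − 0.5|); no haplotype phasing
is attempted.

CBS: recursive maximal circular t-statistic splits, permutation p < 0.01
(1000 permutations, early stop once non-significance is certain), ≥ 5
SNPs per segment, run independently on LRR (all SNPs) and mirrored BAF
deviation (het SNPs); breakpoint union cuts the profile, so
allelic-imbalance-only events (copy-neutral LOH) survive a flat LRR
track. The t-statistic uses the segment's global SD; the permutation test
calibrates whatever statistic is used, and single-changepoint behavior is
pinned against an exhaustive-scan oracle (±3 SNPs).

Ploidy/purity fit: grid α ∈ [0.2, 1.0] step 0.01, ψ ∈ [1.5, 5.0] step
0.05; lattice states (n_total ≤ 8, n_minor ≤ n_total/2) with

    E[LRR]    = log2((α·n + 2(1−α)) / (α·ψ + 2(1−α)))
    E[BAFdev] = |α·n_B + (1−α) − (α·n + 2(1−α))/2| / (α·n + 2(1−α))

and score Σ_seg n_snps · min_state d². Two numerical safeguards matter:

* **LRR winsorization at ±3** (observed and expected): at high purity a
  homozygous deletion drives depth → 0 and LRR → −∞; unbounded residuals
  there would otherwise dominate the whole fit.
* **Low-ploidy preference.** The lattice is exactly invariant under
  (α, ψ) → (α/(2−α), 2ψ) with doubled states, and denser high-ploidy
  lattices fit residual noise strictly better, so a pure argmin
  systematically drifts to inflated ploidies. The reported solution is
  the lowest ploidy whose best score is within `best + 3·Σ n·SEM²` (the
  expected residual of a correct model, computed from per-segment
  standard errors of the mean) or within a 3× ratio as fallback. This is
  the parsimony preference ploidy callers generally apply. The fit is
  flagged ambiguous when purity is genuinely unidentifiable (score
  exactly flat across α, e.g. an all-normal profile), and scaled
  higher-ploidy alternatives are always reported among the candidates.

State assignment per segment is the nearest lattice point under the
fitted (α, ψ); ties break to the lowest total then the highest minor copy
number (parsimony toward normal), and distances above 0.5 set an outlier
flag rather than dropping the segment. Aberration labels use the rounded
ploidy: gain ≥ ψ+1, loss ≤ ψ−1, high-level amplification > ψ+2,
homozygous deletion = 0, LOH at minor = 0, copy-neutral LOH additionally
at total = ψ. Thresholds are fixed integers (configurable), not tuned per
sample. Subclonal copy-number fractions and germline CNVs are out of
scope.

## ITD screen

Input is a per-position mutated-base count table over an extended window
around the FLT3 duplication hotspot (hg19 chr13:28608150–28608349;
configurable). The flag fires on a run of ≥ `min_width` (10) consecutive
positions with mutated fraction ≥ `min_fraction` (0.05). This replaces a
manual read-level review step with an explicit, monotone rule; the call
reports its evidence (peak fraction, run width) because it is a trigger
for targeted review, not a genotype. Zero coverage yields an unflagged
call with a warning. No duplication length or allele ratio is
reconstructed.

## Progression trees

Harmonization first discards events detected in one tumor but covered by
fewer than 10 reads in the other (absence may be purely technical). The
remaining somatic events partition into common / diagnosis-specific /
relapse-specific; copy-number aberrations are matched across samples by
reciprocal overlap ≥ 0.5 **and** identical fitted states (segmentation
jitter must not split a truly shared event; equal-interval segments with
different states are reported discordant). Modes: linear iff nothing is
diagnosis-specific (the ancestor *is* the diagnosis clone and the nodes
merge); else ancestral iff shared non-fusion coding events ≤
`ancestral_max_shared` (default 5, reported with every call); else
branched. The threshold is an explicit surrogate for "no or very few
shared alterations" — no principled universal constant exists, so it is
configurable and the call is reported alongside the count it was based
on. The PML/RARA fusion is an input annotation (breakpoint tag bcr1/2/3),
shared by construction, and never counted. Edge counts report
protein-coding mutations (missense, nonsense, splice, frameshift,
in-frame indel) with all-event counts retained; driver annotation is
list-based (FLT3, WT1, NRAS, KRAS, RARA, NT5C2, NSD1, SALL4, MED12,
KDM6A, ASXL1, ETV6, MYC by default), not discovery-based.

## Synthetic trios

The generator emulates the study design on a 13-chromosome, 30-Mb-each
mini-genome: a germline SNP background (default 2000 SNPs, 2/3
heterozygous; 5% "rare" with population AF ≤ 1% or missing to exercise
the remission gate rather than the population filter), clone-structured
somatic mutations (ancestral / diagnosis-specific / relapse-specific,
placed ≥ 1 kb apart and outside CNA spans unless injected), per-site
depth ~ Poisson(mean 91), alt reads ~ Binomial(depth, p) with p from the
CCF formula and a symmetric per-base error rate of 0.001 (so remission
occasionally shows nonzero alt reads, exercising the strict < 0.05
bound). Default purities are 0.90 (diagnosis) and 0.85 (relapse) — APL
blast fractions are typically high; cohort simulation draws purities
uniformly in [0.65, 0.95]. Mode presets put the diagnosis coding burden
at ~12–13 mutations with ~3 acquired at relapse; cohort burdens are drawn
Poisson around medians 12.5 and 3. Branched trios are constructed with at
least 7 shared coding events, matching a branched topology's substantial
shared trunk and keeping truth away from the ancestral boundary.

Copy-number signals are emitted for a separate evenly spaced SNP grid
(default 1500 SNPs, 70% heterozygous) with tumor depth scaled by local
copies over sample ploidy and B-allele counts drawn at the
state-expected fraction with random allele polarity. `inject_cn_loh`
relocates one mutation of a chosen clone into a (2,0) segment at
multiplicity 2 — the mutant-allele duplication pattern. The ITD signal is
*read-coherent*: the carrier read count for the duplication block is
drawn once (ITD-supporting reads span the whole short block), then
per-position depth jitter and background errors are added; independent
per-position draws would understate run lengths and misrepresent the
physical signal. The bait BED covers every emitted site except a 2%
off-bait fraction, exercising the bait filter.

What the generator does **not** emulate: mapping artifacts, strand bias,
GC- and capture-efficiency-driven depth heterogeneity (depth is flat
Poisson, so "fraction of targets ≥ 25×" sits near 1.0 rather than the
sub-1 values real capture data show), mutational signatures, read-level
FASTQ/BAM structure, and subclonal copy number. Passing tests therefore
establish the correctness of the *rules and estimators* under the stated
sampling models, not robustness to real-data artifacts.

## Problem sizes and determinism

Tests and the acceptance script scale the simulations to what the checks
need: 120–500 germline SNPs per trio for filter/tree behavior (the rules
are per-site, so the SNP count only widens counting noise), 1500 SNPs per
copy-number profile (~115 per chromosome, ≥ 30 per simulated event), 500
replicates per CCF grid cell, 200 ITD replicates, 300 trios for mode
recovery and an 18-trio cohort shaped 9/4/5. Every random draw flows from
an explicit seed; reruns are byte-identical (floats are written at fixed
precision), which the suite asserts at file level.

## Known limitations

* Purity is unidentifiable from a copy-number-flat genome; the fit then
  reports ψ = 2 with the ambiguity flag, and CCF estimation should be
  given an external purity via the override.
* The branched/ancestral boundary is a configurable count, not a model;
  calls within ±2 events of the threshold deserve manual review.
* Multi-nucleotide substitutions are represented as independent SNVs.
* The ITD screen reports evidence only; it neither sizes the duplication
  nor quantifies its allele ratio.
* CCF assumes one clonal copy-number state per segment; mutations on
  subclonal segments get the clonal-state correction.
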