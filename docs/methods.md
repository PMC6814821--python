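# Methods

`sweepscan` detects positive selection in one of two diverged populations
("highland" vs "lowland") from phased, ancestral-polarized SNP haplotypes,
combines several per-SNP selection statistics into a single composite score,
aggregates it per gene, and tests whether predefined gene sets (e.g. cancer
gene catalogs) are enriched for selection signals. Every stage is validated
against a built-in forward Wright–Fisher simulator with exact ground truth.

## Per-SNP statistics

**Derived allele frequency (DAF).** Haplotypes are coded 0 = ancestral,
1 = derived after polarization against the ancestral allele (VCF `AA` INFO
key or a side table). DAF is computed per population with missing calls
removed from the denominator. ΔDAF = DAF(highland) − DAF(lowland) ∈ [−1, 1].

**F_ST.** The Weir–Cockerham (1984) variance-components estimator θ̂,
computed per SNP. Because the input is phased, the default variant treats
each haplotype as an independently sampled allele (one-way ANOVA on allele
indicators with r = 2 groups); the classical diploid-genotype variant with
the observed-heterozygosity term is available via `variant="diploid"`.
θ̂ is reported unclipped — slightly negative values are the estimator's
normal finite-sample behaviour near zero differentiation (≈ −1/(n_c − 1)
when frequencies are equal) — and floored at 0 only when converted to a
selection probability, since negative differentiation carries no selection
evidence. Sites monomorphic in both populations are 0/0 and reported NaN.

**EHH, iHH, iHS.** EHH of a core allele at flanking site *s* is the
probability that two randomly drawn carriers are identical over the
interval core→*s*: Σ_h C(n_h,2)/C(n,2) over distinct extended haplotypes.
iHH is the trapezoidal integral of EHH over physical distance (bp), each
direction truncated at the first site where EHH < 0.05 or at an inter-site
gap > 200 kb (the site is flagged). iHS = ln(iHH_ancestral/iHH_derived),
z-scored within 50 equal-width derived-allele-frequency bins; bins with
fewer than 20 sites are merged rightwards. Sites where either allele's
curve reaches a chromosome edge before decaying are dropped, not
extrapolated: extrapolation would bias iHH precisely at the strongest
cores. Physical rather than genetic distance is used throughout — no
genetic maps are assumed for the species of interest, and a constant
per-bp rate would rescale both iHH values equally, cancelling in the
log-ratio.

**XP-EHH.** For each core site, EHH is computed over *all* haplotypes of
each population (partitioned by the core allele, so EHH(0) is the core's
homozygosity), and XP-EHH = ln(iHH_A/iHH_B), z-scored genome-wide.
Critically, both populations' integrals are truncated at the *same*
boundary: the point where the pooled two-population EHH drops below the
cutoff. Truncating each population at its own decay point would censor
exactly the swept population — after a completed sweep its EHH can stay
above the cutoff to the chromosome edge — and systematically discard the
strongest signals. Positive values indicate extended haplotypes (recent or
ongoing sweep) in population A.

## The composite (iFXD)

Each per-SNP statistic is converted to a probability of positive selection
Ps and the composite is the product of odds over the n methods in use:

    iFXD = ∏_{i=1..n} Ps_i / (1 − Ps_i)

Ps is the one-sided empirical rank probability r/(N+1): r is the SNP's
rank (average ranks for ties) among the N genome-wide non-missing values,
oriented so that larger means more selection-like (F_ST floored at 0,
direction high; ΔDAF high; XP-EHH high; iHS by absolute value). This
choice is assumption-free, keeps every Ps strictly inside (0, 1) — no
infinite odds — and makes iFXD a pure rank composite; a parametric
alternative (normal tail of the z-score, clipped to [1e−6, 1−1e−6]) is
provided for comparison. The default method set is {F_ST, XP-EHH, ΔDAF};
{F_ST, XP-EHH, iHS} suits a single-population-history scan where within-
population haplotype structure is informative. Sites missing any method's
Ps are skipped and counted.

A gene's score is the arithmetic mean iFXD of the SNPs strictly inside its
interval (no flank by default); genes are ranked by that mean (rank 1 =
highest, ties broken by gene id) and a top-k report (k = 2 by default) is
emitted. Per gene the scan also reports F_ST_max and the counts of SNPs
with |iHS| or XP-EHH beyond a significance threshold (2 SD by default, the
conventional cutoff for these standardized statistics).

## Window scan and empirical p

Windows of 50 kb stepped by 25 kb (both configurable) tile each chromosome
from position 0; a window's score is the mean statistic over its SNPs
(empty windows are omitted). The empirical p of window w is the fraction
of windows — w itself included — whose mean is at least mean_w, out of
N + 1. Self-inclusion plus the +1 denominator keeps p strictly inside
(0, 1), so −log10 p is always finite; the single best of 99 windows gets
p = 1/100.

## Gene-set enrichment

Mann–Whitney U (set vs all other scored units), one-sided "set > other" by
default since the hypotheses are directional. The p-value is exact by full
enumeration when the pooled sample has ≤ 12 tie-free observations,
otherwise the normal approximation with tie and continuity corrections.
Gene-level comparisons use any per-gene summary (F_ST_max, significant-SNP
counts, mean iFXD); SNP-level comparisons contrast SNPs inside set genes
against SNPs inside other genes. Intergenic SNPs are excluded by default —
the contrast of interest is gene set versus other genes — but can be
folded into "other". SNPs inside both a set and a non-set gene count as
set SNPs (deterministic tie-break). No multiple-testing correction is
applied across sets; raw p-values are reported.

## Clinical contingency module

Positivity percentages are 100·a/n rounded half-up to one decimal
(matching how such tables are conventionally printed). 2×2 association
offers Pearson chi-square, Yates-corrected chi-square (default) and
Fisher's exact test; the odds ratio is the cross-product ad/bc, reported
as missing whenever any cell is zero (no Haldane correction by default).

## The simulator

A forward Wright–Fisher model on a fixed site grid along one chromosome:
an ancestral population evolves for a burn-in, splits into highland and
lowland copies that drift independently for T generations, and each
transmitted gamete recombines with a Poisson number of crossovers. Initial
variation is seeded by drawing per-site derived-allele frequencies from
the standard neutral spectrum (P(count = i) ∝ 1/i) for a fraction of sites
(80% by default); seeding stands in for the site's single historical
mutation event, since reaching mutation–drift equilibrium from scratch
would need ~4N generations. The remaining sites can each receive exactly
one forward-time mutation at rate μ, with the pre-mutation allele recorded
as ancestral — polarization is perfect by construction.

The optional sweep forces one grid site monomorphic-ancestral at the
split, injects derived copies into the highland population at a starting
frequency (0.05), and applies genotype fitnesses 1 : 1+hs : 1+s to parent
sampling. Runs are restarted from the split snapshot until the allele ends
at ≥ 80% frequency (`min_final_freq`): the scenario models the completed
sweeps a scan is built to find; conditioning on mere non-loss leaves many
replicates where selection has barely acted, which is a different
question. Restart counts are reported in the truth record.

Default scale and why: 500 diploids per population, 1 Mb chromosome, 2000
grid sites, 100 burn-in + 150 post-split generations, 0.2 crossovers per
gamete, s = 0.05, h = 0.5. Post-split drift then gives E[F_ST] ≈ T/2N =
0.15 — the range seen between highland and lowland livestock populations —
with drift variance low enough that drift-fixed haplotype blocks do not
routinely mimic sweeps, while r·t over the sweep's rise leaves a swept
haplotype block tens of kb wide, resolvable on the 500 bp site grid. One
replicate simulates in ~2 s and scans in ~4 s on one core. Genes are tiled
along the chromosome (20 kb genes, 5 kb gaps), a configurable fraction is
labeled the "cancer" set, and the sweep gene can be forced into or out of
the set. All randomness flows from the single config seed; identical
configs produce byte-identical output.

**What the simulator does not emulate.** SFS-seeded sites start in linkage
equilibrium, so background LD is built only by burn-in drift and is weaker
than in real genomes; there is no migration, no background selection, no
demography beyond one clean split, and no mispolarization. Passing the
recovery tests therefore shows the statistics respond to the modelled
sweep signature under moderate drift — not that real-data confounders
(ascertainment, demography, polarization error) are handled.

**Known limitation — iHS at desk scale.** On a 1 Mb toy chromosome a large
fraction of cores are censored by the edge rule: carriers of one allele
often share haplotypes to the chromosome end, which on real 100+ Mb
chromosomes is rare. iHS output is therefore sparse on default simulated
data (it gains support at higher recombination rates), and the composite's
haplotype information is carried by XP-EHH, whose pooled-EHH truncation is
robust to this. This is an edge effect of chromosome length, not of the
estimator.

## Numerical and degenerate-input conventions

Missing genotypes: excluded from frequency denominators; haplotypes with a
missing call inside the spanned interval are removed from that core's
carrier set (homozygosity is undefined through a missing call), and
integration stops if fewer than two carriers remain. Multi-allelic and
non-SNP records are dropped, never split. All-identical statistic vectors
yield Ps = 0.5 everywhere with a warning. Empty windows and zero-SNP genes
are omitted and counted, never scored as zero. Internal coordinates are
0-based half-open; VCF (1-based) and BED (0-based) are converted at the
I/O boundary, eliminating ±1 drift.

## Validation scheme

Every estimator is checked against an independent oracle that shares no
code with the implementation: Weir–Cockerham against a standalone
transcription of the 1984 variance components; EHH and XP-EHH against
quadratic-time direct pair counting; exact Mann–Whitney against full
enumeration of rank assignments; Fisher against hypergeometric
enumeration. Scale-free identities (iFXD(0.5,…) = 1, iFXD(0.9,0.9,0.9) =
729, log iFXD = Σ logit Ps, antisymmetries under population swap) are
asserted directly. Signal recovery uses 20 seeded sweep replicates
(s = 0.05) requiring the swept gene in the top 2 by mean iFXD in ≥ 80%,
and 200 reduced-size neutral replicates (40 diploids, 400 sites) with
random gene-set labels requiring uniform enrichment p-values and a
calibrated 5% type-I rate; the reduced size keeps 200 independent
replicates within a desk-scale run while leaving the test's null exact.
`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all of these from scratch.
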