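# Methods

## Scope and data model

panelpop analyzes panels of (near-)fully inbred lines genotyped at
biallelic SNPs with genetic-map (centimorgan) coordinates. Because an
inbred line is homozygous at essentially every locus, its genotype
identifies its haplotype allele; all estimators therefore treat a line as
a single haploid allele copy. Heterozygous calls — residual
heterozygosity in such panels is a fraction of a percent — are recoded to
missing before any statistic is computed (`recode_het_missing`); a
configuration switch on the frequency routines (`het="half"`) instead
counts a heterozygote as half a copy of each allele, for users who prefer
dosage frequencies.

Allele frequency at a locus is the fraction of counted copies carrying
allele 2; MAF = min(p, 1−p). The MAF filter is strict by default
(`MAF > maf_min`, keeping alleles *above* the cutoff), with an inclusive
option. Monomorphic loci always fail the MAF rule for positive cutoffs.
Loci are kept in a canonical order — (genome, chromosome, cM, locus id) —
so that windows, pair distances and greedy thinning are deterministic;
cM ties are broken by locus id.

## Diversity

PIC = 1 − Σ pᵢ², computed from the two allele frequencies per locus. For
biallelic loci this equals expected heterozygosity and is bounded by 0.5.
Within a stratum (population, growth-habit group, or the whole panel),
loci monomorphic in that stratum contribute PIC = 0, MAF = 0 and one
allele to the stratum means and stay in the denominator, so means are
comparable across strata sharing a locus panel. A locus with no observed
call in a stratum is counted as monomorphic. Strata below `min_lines`
(default 5) are excluded with a warning: polymorphism proportions from a
handful of lines are not comparable with those from dozens.

MAF spectra bin the group-wise MAF of polymorphic loci into bins of width
0.05 on [0, 0.5] (half-open bins, closed last bin so MAF = 0.5 is
counted). Two spectra are compared by a Pearson chi-square on the 2×B
contingency table, dropping bins empty in both groups.

## Weir–Cockerham F_ST on haploid copies

For r groups with sizes nᵢ and allele-2 frequencies p̂ᵢ at a locus
(N = Σnᵢ, p̄ the weighted mean):

    MSP = Σ nᵢ(p̂ᵢ − p̄)² / (r − 1)
    MSG = Σ nᵢ p̂ᵢ(1 − p̂ᵢ) / Σ(nᵢ − 1)
    n_c = (N − Σnᵢ²/N) / (r − 1)
    θ̂  = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

This is the ANOVA estimator specialized to haploid samples, which is the
correct form once heterozygotes are removed; users expecting the diploid
form should note the difference. θ̂ equals 1 exactly when groups are
fixed for alternative alleles and may be negative when the among-group
mean square is small. The estimate is flagged undefined when the pooled
locus is monomorphic, fewer than two groups have data, or the denominator
vanishes; undefined loci are excluded from windows, summaries and the
bootstrap, with counts logged.

### Hierarchical variance components

Allelic variance is partitioned by a nested random-effects ANOVA on the
0/1 allele indicators: within populations, among populations within
growth-habit group, among groups. Unbalanced designs use the standard
nested-ANOVA coefficients (the k-factors built from Σnᵢ² terms).
Components are estimated per locus, summed over loci, and negative sums
are truncated to zero (flagged) before conversion to percentages, so the
reported percentages are non-negative and sum to 100. When only one
group is present the among-group stratum collapses and is reported as 0
with a flag. Populations below `min_lines` are dropped first.

### Sliding-window scan and bootstrap threshold

Window means are computed over W = 5 consecutive defined loci per
chromosome at step 1 (the window never spans a chromosome; chromosomes
with fewer than W defined loci yield no windows). The null threshold is
the 95th percentile of B = 1000 bootstrap means, each of W loci drawn
with replacement from *all* defined loci genome-wide — a null of "W
random SNPs" that deliberately ignores linkage, so the scan asks whether
a window of adjacent SNPs is more differentiated than a random SNP set.
Multiple testing across windows is handled only through this single
genome-wide threshold; no per-window p-values are produced. Maximal runs
of consecutive above-threshold windows are merged into intervals
(first-window start to last-window end), reported with the mean of their
member window means. The scan is a screen for candidate regions, not a
formal test for selection.

Because single-locus θ̂ values are approximately independent across loci
under the generating model (population frequencies are drawn
independently per locus), about 5% of windows exceed the threshold in the
absence of planted differentiation — the calibration the acceptance
script measures.

## Linkage disequilibrium

Two-locus haplotype counts are read directly from the homozygous
genotypes of lines complete at both pair members (no EM phasing — with
<1% heterozygosity the inbred shortcut is exact to rounding). Pairs with
fewer than `min_complete` (default 10) complete lines, or with a margin
monomorphic among them, are skipped and logged.

* **r²** = D²/(p(1−p)q(1−q)) with D = f₁₁ − p·q; identical to the squared
  Pearson correlation of the two 0/1 allele vectors.
* **|D′|** = |D|/D_max with the usual frequency bound. Its 90% confidence
  interval normalizes the multinomial likelihood of the observed table
  over a 1001-point |D′| grid (margins fixed at their MLEs, sign of D
  fixed at the observed sign) and reads the bounds at cumulative 5% and
  95% — the Gabriel/Haploview convention.
* **Significance** is the two-sided Fisher exact probability of the 2×2
  table (the exact LD test for haploid data reduces to it): the sum of
  hypergeometric probabilities of all tables, margins fixed, whose
  probability does not exceed the observed table's (relative tie
  tolerance 1e-7).
* **FDR** is Benjamini–Hochberg step-up at q = 0.01, applied once over
  the whole pair universe (intra- and inter-chromosomal together) per
  panel analyzed. q-values are the monotone-adjusted min(m·p₍ₖ₎/k).
  Because the significance cutoff that the exact test + FDR implies is
  panel-specific, the summary also reports the realized cutoff — the
  smallest r² among significant pairs.

The **extent of significant LD** is summarized as the mean and median cM
distance of significant intra-chromosomal pairs. This is a per-pair
definition; a per-locus variant (each locus's maximum significant
distance) is available behind the `per_locus` flag, since either reading
of "extent" is defensible. **Background LD** is the 95th percentile of
all inter-chromosomal r² — an empirical noise floor for association.

The **decay curve** fits a locally weighted linear regression (loess,
degree 1, tricube weights, span 0.5 by default) of r² on distance.
"Initial LD" is the fitted value at the smallest observed distance —
the anchor has to be defined somewhere, and the smallest observed
distance is the only model-free choice — and the half-decay distance is
where the fitted curve first drops to half that value (linear
interpolation between grid points; reported as not-reached/`inf`
otherwise). Loess has a downward boundary bias at zero distance for
convex decay profiles, which biases half-decay estimates upward by a few
tenths of a cM at moderate spans; smaller spans reduce it at the price of
noise.

**Gabriel blocks**: a pair is "strong LD" if its |D′| CI is
[≥0.70, ≥0.98] and "strong recombination" if the upper bound is <0.90;
a candidate block is a map-contiguous locus run whose outermost pair is
strong-LD, accepted when ≥95% of its informative pairs are strong-LD.
Candidates are searched within a 30 cM span, and overlaps are resolved
longest-span-first with leftmost tie-break. All four thresholds and the
span are parameters (`GabrielParams`); the defaults are the published
convention of the method.

## The synthetic-panel generator

The generator emulates the structure of a US/CIMMYT spring–winter wheat
cultivar panel: 478 lines in 17 breeding populations (9 winter totalling
237 lines, 8 spring totalling 241, with the observed per-program sizes),
21 chromosomes of 150 cM in three genomes, ~42 loci per chromosome before
ascertainment, 0.5% heterozygous and 0.9% missing calls, and MAF-0.05
ascertainment — these defaults *are* the study conditions and are not
tuned per analysis.

1. **Ancestral frequencies** p ~ Uniform(0.05, 0.95) per locus.
2. **Population frequencies** follow Balding–Nichols:
   qᵢ ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so Var qᵢ = F·p(1−p) and F is the
   target F_ST among populations (default 0.10, in the range such panels
   show among breeding programs).
3. **Planted regions** shift q by +δ in every winter population and −δ in
   every spring population (clipped to [0.02, 0.98]) inside declared cM
   intervals. The defaults plant a strong (δ = 0.40) region on 5A at
   80–138 cM and two moderate (δ = 0.30) regions on 2B and 2A — shaped
   like the flowering-time architecture a spring/winter contrast detects.
4. **Founder pools**: each population receives `n_founders` (default 10)
   haplotypes. The pool carries round(q·n_founders) copies of allele 2
   per locus — stochastic rounding, so the pool frequency is unbiased for
   q — placed on random founders independently per locus. Matching the
   pool frequency to q (rather than drawing founder alleles Bernoulli(q))
   removes founder-pool drift: with Bernoulli pools the realized
   among-population variance would be inflated by ≈(1−F)/n_founders,
   destroying the exact recoverability that is the generator's purpose.
   The residual quantization noise inflates realized F_ST by roughly
   E[c(1−c)]/n_founders² relative terms — under +0.01 at the default
   pool size.
5. **Line haplotypes** are founder mosaics: walking loci in map order,
   the founder identity switches between adjacent loci with probability
   r_g = ½(1 − (1−2r)^g), the Haldane recombination fraction
   r = ½(1 − e^(−2d/100)) compounded over g = `generations` (default 5)
   meioses; chromosome starts draw a fresh founder. Shared founder
   identity along the mosaic is what creates distance-decaying LD: the
   founder-identity correlation halves every ≈ 100·ln2/(2g) ≈ 7 cM at the
   default, and the short-range r² level within a population is ≈
   1/n_founders. Pooling populations with independent founder pools
   dilutes r², as it does in real multi-program panels.
6. **Noise and ascertainment**: each call flips to heterozygous with
   `het_rate` and to missing with `missing_rate` (independent draws,
   missing wins); loci below `ascertain_maf_min` pooled MAF are then
   dropped, mirroring a fixed assay that reports only panel-polymorphic
   SNPs. Truth (ancestral and population frequencies, planted flags,
   realized per-locus F_ST, kept flags) is recorded before these steps.

All randomness flows from one seed through named per-stage child streams
(`numpy.random.SeedSequence.spawn`), so a config reproduces a
byte-identical panel and stages can be re-derived independently.

### What the generator does not emulate

No coalescent genealogy, no selection dynamics, no pedigree structure, no
allele-frequency correlation between linked loci at the population level
(LD is purely within-population founder structure), and no genome-specific
diversity differences (the real D-genome is less diverse and more
LD-laden than A and B). Passing tests on synthetic panels therefore
validate the estimators and the pipeline plumbing, not claims about any
particular crop's history.

## Numerical conventions

* Undefined θ̂ (pooled-monomorphic locus, degenerate denominator) is NaN
  with a `defined=False` flag, excluded downstream with logged counts.
* Negative summed variance components truncate to 0 with a flag.
* Bootstrap percentiles use numpy's linear interpolation; a degenerate
  bootstrap distribution returns its constant exactly.
* Window membership, thinning and block search follow canonical locus
  order; all tie-breaks are documented above and deterministic.
* The D′ CI clips haplotype frequencies at 1e-12 before taking logs, so
  boundary tables (a zero cell) are handled without special cases.
* TSV writers emit UTF-8 with '#' comment headers carrying the package
  version, seed and config hash; floats print via `%.10g` for
  reproducible bytes.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use deliberately scaled
problem sizes chosen to exercise every code path with comfortable
statistical margins: estimator recovery on 8 populations × 30 lines ×
500 loci (three seeds per F_ST target), scan power and null calibration
on 200-line × 200-locus panels over 20 seeds each, decay-curve checks on
a few thousand synthetic pairs, and pipeline determinism on a 100-line ×
200-locus run. Full-size panels (478 × 850) run the complete pipeline in
minutes, dominated by the all-pairs exact tests.

## Known limitations

* The all-pairs LD stage is quadratic in loci with a Python-level pair
  loop; panels beyond a few thousand mapped SNPs need chunking or
  pre-thinning.
* The exact test's tie handling uses a 1e-7 relative tolerance; p-values
  are reproducible but may differ in the last digits from
  implementations with other tie conventions.
* The D′ CI fixes allele frequencies at their MLEs (profile rather than
  joint likelihood), as the published block-detection convention does.
* `hierarchical_components` assumes every population nests in exactly one
  group; admixed group assignments must be resolved upstream.
* With `het="half"` dosage frequencies, the haploid Weir–Cockerham form
  is still used; for panels with substantial heterozygosity a diploid
  estimator would be preferable and is not provided.
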