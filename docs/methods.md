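# Methods

## The inference problem

A single family cross — father, mother, and tens of phenotypically sexed
offspring — is genotyped at thousands of short RAD loci. If one
chromosome pair carries a sex-determining (SD) locus inside a region of
suppressed recombination, three observable signatures follow, and the
package measures all three:

* alleles on the sex-limited haplotype (Y under male heterogamety, W
  under female heterogamety) co-segregate with offspring sex, producing
  between-sex allele-frequency differentiation at linked SNPs;
* the zygosity structure at such SNPs is asymmetric between parents
  (heterogametic parent het, homogametic parent hom) and between
  offspring sexes;
* loci physically restricted to one haplotype (Y/W-limited, or deleted
  from it) show sex-specific read depth.

## Association statistics

Offspring (never the parents) form the two "populations". Each
non-missing diploid call contributes two alleles to a 2×2 allele × sex
table. The differentiation statistic is the Wright/Nei fixation index

    F_ST = (H_T − H_S) / H_T,

with H_S the unweighted mean of the two within-sex expected
heterozygosities 2p(1−p) and H_T computed from the unweighted mean
allele frequency; F_ST = 0 when H_T = 0. Parents are excluded because a
single extra diploid per pool adds no segregation information and would
dilute the offspring null. Note a single-cross ceiling: at a perfectly
XY-linked site (all sons Aa, all daughters AA) p_M = 0.5 and p_F = 0, so
F_ST = 1/3, not 1. This is why ranking — the quantity that feeds every
downstream step — uses the exact-test p-value, with F_ST reported and
p-gated (zeroed when p > 0.05, configurable) for compatibility with
population-genomics conventions.

The two-sided Fisher exact test enumerates the full hypergeometric
support of the table's margins and sums the probabilities of all tables
no more probable than the observed one. Ties are compared with an
absolute tolerance of 1e-12; for tables of the sizes seen here (total
≤ ~110 alleles) distinct hypergeometric probabilities differ by far more
than that, so the tolerance only absorbs floating-point noise. Any zero
margin returns p = 1 by convention. The implementation uses
`scipy.stats.hypergeom` for the probabilities only; the test logic is
validated in the suite against an independent exact-rational enumeration
(`math.comb` + `fractions`) on every 2×2 table with total ≤ 30.

## Inheritance-pattern classification

A site is XY-informative when the father is heterozygous and the mother
homozygous and the offspring follow the expected zygosity (sons het,
daughters hom); ZW mirrors it. Only het/hom structure matters — which
homozygote the homogametic parent carries does not. Concordance is the
fraction of non-missing offspring matching the expectation; missing
calls leave the denominator. The default calling threshold of 0.9
tolerates occasional sexing errors and marker–SD recombinants (the kind
of imperfect linkage real crosses show) and can be raised to 1.0 for
strict mode. Phase matters: if the father's Y-borne allele equals the
mother's allele, the fingerprint inverts (sons hom, daughters het) and
the site is simply left uncalled rather than misread; the suite checks
that relabeling sexes and parental roles maps XY calls to ZW calls
exactly.

The heterogamety verdict over the top-N (default 100) sites requires the
majority pattern to lead its mirror by at least a factor of two;
otherwise the verdict is "ambiguous", and "none" when neither pattern
occurs. The factor-two margin is a deliberate design choice where the
field practice is a qualitative read-off; it is conservative and cheap
to change.

## Coverage analysis

Per locus, son and daughter mean depths are simple arithmetic means over
offspring of each sex. Gates are applied in a fixed order: first the
low/high filters (overall mean < 1: spurious; > 500: repeat-like), so a
repeat locus can never be called male-only; then male-only (daughter
mean < 2 and son mean > 5); then female-biased (daughter/son ratio > 1.5
with daughter mean > 2). The "overall" mean defaults to the mean of the
two sex means (a "mean of all means"); per-sex gating is a config
switch, since published descriptions of such filters are often ambiguous
on this point. A zero son mean with covered daughters yields an infinite
ratio and a female-biased call only if the daughter mean clears the
spurious-read gate.

Scatter reference slopes are derived from genome-wide means: autosomal
slope = (daughter grand mean)/(son grand mean), X-limited = 2× that,
W-limited = 0.5× — absorbing library-size and sample-size imbalance.

## Chromosome-level inference

Enrichment of a coverage class on a chromosome uses the 2×2 table
[[k, K−k], [n−k, (N−K)−(n−k)]] over placed loci only (k of the
chromosome's n placed loci in the class; K of N overall). Unplaced loci
are excluded from every cell; the background set is therefore always
explicit. Results sort by p with ties broken by natural chromosome-label
order.

The SD region is called from sliding windows (default 2 Mb, step =
window/4) counting SNPs with association p < 0.001. The densest window
seeds the call — ties resolve to the first chromosome in label order and
the lowest start — and the interval grows to the union of windows
overlapping it whose count stays ≥ 50% of the seed's. No call is made
when the best window has fewer than 3 hits. Window size, step fraction,
extension ratio and the hit floor are exposed in the configuration; they
were chosen once as round values that resolve a ~14 Mb region with
2–4 Mb granularity, and the replicated self-test measures (rather than
assumes) their recovery behavior.

## The cross simulator

The generator emulates the study conditions end to end:

* **Design.** Defaults: 28 sons + 27 daughters (the lab cross;
  `chipwa_design()` gives the 20 + 20 wild cross), 10 chromosomes of
  30 Mb, 1,000 RAD loci per chromosome — one per 30 kb, the SbfI site
  density of the emulated libraries — one SNP per locus, XY system with
  the SD region at 6.8–20.3 Mb of LG5.
* **Meiosis.** Poisson crossover count per chromosome (default 2.0
  Morgans), uniform positions, no interference. Crossovers inside the SD
  region of the heterogametic parent are kept with probability
  `sd_recomb_suppression` (default 0: complete suppression). Offspring
  sex is fixed by design; the heterogametic parent's gamete is resampled
  until the haplotype transmitted at the SD midpoint matches (Y to sons,
  W to daughters). The 2-Morgan default makes association significance
  decay on the chromosome scale — significant SNPs extend a few Mb
  beyond the suppressed region, reproducing the observed geometry of a
  dense in-region peak with a broader shoulder — and sits within the
  1–2 crossovers/chromosome/meiosis range typical of teleost linkage
  maps. At 1 Morgan the entire 30-Mb chromosome would remain in near-
  perfect linkage with the SD locus and region localization would be
  meaningless.
* **Hemizygous loci.** Within the SD region, `frac_y_limited` (default
  0.1) of loci exist only on the sex-limited haplotype and
  `frac_x_limited_diff` (default 0.1) are deleted from it. Both are
  emitted the way a diploid caller would see them: Y/W-limited loci have
  no genotype rows at all (depth only); one-dose loci emit genotypes
  with hemizygous individuals encoded as homozygous for their single
  allele. Copy number per individual is derived from the actually
  transmitted haplotype at the locus, which reduces to the sex-based
  expectation under full suppression and stays correct under partial
  suppression.
* **Depths.** Negative binomial with mean `depth_mean`/2 per haplotype
  dose (default diploid mean 20) and dispersion 5 (variance m + m²/5,
  the overdispersion of real RAD libraries; Poisson is the dispersion→∞
  limit). Individuals with zero doses still draw from a mean-0.1
  contamination floor, so "absent" is noisy — exactly the failure mode
  the < 1 and < 2 coverage gates exist for.
* **Noise.** Genotyping errors re-draw a call uniformly among the other
  two states at rate 0.01; calls go missing at rate 0.02. Parental
  allele frequencies are uniform on [0.1, 0.5].
* **Truth.** Every locus gets a class (Y_LIMITED, X_DIFF, SD_LINKED,
  AUTOSOMAL) and every SNP a Haldane recombination fraction to the SD
  midpoint (map rate scaled by the suppression factor inside the
  region), enabling the concordance-vs-linkage and recovery checks.

Identical seeds reproduce all outputs bit-for-bit.

### What the simulator does not model

Read-level artifacts (no FASTQ), restriction-site polymorphism and locus
dropout, spatially clustered cut sites, PCR duplicates, polygenic or
environmental sex determination, sex reversal, B chromosomes, and
reference-placement error (the placement table is exact). Passing the
replicated self-tests therefore shows the statistical machinery recovers
a planted monogenic SD architecture under realistic depth and error
noise — not that every real cross, with mis-sexed individuals or
polygenic systems, will behave as cleanly.

## Problem sizes and numerical choices

The replicated self-tests use the full default design (10,000 loci,
~10,000 SNPs, 55 offspring; ~0.5 s per replicate): 100 replicates for
chromosome/region recovery, 20 error-free crosses per system for
heterogamety discrimination, 50 depth-only replicates (no SNPs
simulated) for classifier operating characteristics, and one 10,000-SNP
null cross for false-positive control. Exact-test correctness is checked
exhaustively for all 2×2 tables with total ≤ 30 against rational
arithmetic. Deterministic tie-breaks appear wherever ordering matters:
p-value ranking falls back to larger F_ST then site key; enrichment and
region seeding fall back to natural chromosome-label order and lowest
coordinate.

## Known limitations

* Single-family design: the association null is driven by Mendelian
  sampling in one sibship; rates do not transfer to population samples.
* The F_ST variant is the simple heterozygosity-based form, not an
  AMOVA/variance-components estimator; with p-value-driven ranking the
  choice is immaterial downstream, but reported F_ST values are not
  comparable across estimators.
* The region call reports the span of dense significance, which under
  partial linkage is wider than the causal locus; interpret its bounds
  as a shoulder, not a fine-mapping interval.
* Multi-family joint analysis, linkage-map construction and
  kernel-smoothed F_ST are out of scope.
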