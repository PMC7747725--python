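# Methods

## ROH detection model

`rohtrace` detects runs of homozygosity with the incremental
sliding-window scheme used by PLINK's `--homozyg`. For one sample on one
chromosome, every window of exactly `window_snps` consecutive SNPs is
classified *hit* if it contains at most `window_het` heterozygous and at
most `window_missing` missing calls. Each SNP's *hit rate* is the
fraction of hit windows among all full windows overlapping it; the SNP
is eligible when the hit rate reaches `hit_rate_threshold`. Maximal runs
of eligible SNPs are split wherever two adjacent SNPs lie more than
`max_gap_kb` apart, and each piece is reported as a ROH segment iff it
has at least `min_snps` SNPs, spans at least `min_length_kb` and has at
most `density_kb_per_snp` kilobases per SNP. Segment endpoints are the
positions of the first and last SNP of the piece; coordinates are
1-based closed throughout, converted to BED convention only on output.

Parameter presets:

| parameter            | `wgs`   | `chip`  | meaning                              |
|----------------------|---------|---------|--------------------------------------|
| window_snps          | 20      | 20      | SNPs per scanning window             |
| window_het           | 3       | 3       | het calls tolerated per window       |
| window_missing       | 5       | 5       | missing calls tolerated per window   |
| min_snps             | 20      | 20      | minimum SNPs per segment             |
| min_length_kb        | 2.4     | 10      | minimum segment span                 |
| density_kb_per_snp   | 0.12    | 1000    | maximum kb per SNP in a segment      |
| max_gap_kb           | 100     | 100     | maximum adjacent-SNP spacing         |
| hit_rate_threshold   | 0.05    | 0.05    | window hit fraction for eligibility  |

`hit_rate_threshold` is a detector convention, not a published value;
0.05 is the default of the tool family this scan derives from and is
exposed prominently. Chromosome ends use only the windows that exist;
a chromosome with fewer SNPs than one window is evaluated as a single
truncated window so short scaffolds are not silently dropped
(`strict_window=True` disables this and yields no calls there). Density
is evaluated per final segment (`length_kb / n_snps`), not per window,
matching the "at least X kb with a density of 1 SNP per Y kb" reading.
Segment-level het/missing caps exist (`max_segment_het`/`_missing`) but
default to off. Maximal runs are unique, so no tie-breaking arises.

Note one behavioural consequence of the hit-rate mechanism: a SNP needs
only one passing window to be eligible at threshold 0.05, so the
window-level het bound is guaranteed inside reported segments only at
`hit_rate_threshold=1.0`; the property test asserts it there.

`brute_force_roh` re-derives the same definition with explicit Python
loops over every window, SNP and run — written independently of the
vectorised path and restricted to ≤10,000 sites — and the suite checks
exact agreement on hundreds of randomised instances (genotypes,
positions and parameters all drawn at random).

## Consensus regions, specificity, F_ROH

Group consensus is computed at base-pair resolution by an endpoint
sweep over segment boundaries: maximal intervals whose per-bp support
(number of group members with a ROH covering the base) reaches
`min_support` ("all" = group size). The support attached to a region is
the minimum per-bp support across it. Base-pair resolution is strictly
finer than SNP resolution and the regions of interest are kb-scale.

Breed-specificity subtracts, from each consensus region, every base
covered by ROH in at least `max_support_excluded` members of the
excluded group (default 1: any crossbreed overlap removes, the WGS
rule; the chip workflow uses 5). Fragments shorter than
`min_fragment_bp` (default 1000 bp) are dropped to avoid slivers; a
`drop_whole_region` mode removes an overlapped region entirely instead
of fragmenting it, since published region counts can be produced under
either convention. The chip consensus supports both documented modes:
`min_support="all"` and an explicit fraction such as 8 of 19.

`F_ROH` per individual is the summed length of autosomal ROH divided by
`autosomal_captured_bp` (default 2,265,395,079 bp, the captured pig
autosome for a WGS panel); segments on excluded chromosomes (X, Y, Mt,
Un) are ignored and overlapping segments within one sample are rejected
as a caller-contract violation. Breed-level values are arithmetic means
of individual coefficients.

## Enrichment

Gene assignment uses any-overlap (≥1 bp) semantics on closed intervals.
Enrichment of a region gene list against user-supplied gene sets is the
one-sided Fisher exact test on the hypergeometric distribution,
`fisher_p = P(X ≥ k)` for overlap `k`, set size `K`, query size `n`,
background `N`; the EASE score removes one success
(`ease_p = P(X ≥ k−1)`, defined as 1 for `k ≤ 1`) — the conservative
variant used by DAVID-style annotation tools, flagged at the
conventional 0.1 threshold. This is a local replacement for web
annotation services; no multiple-testing correction is applied by
default (published EASE scores are raw), Benjamini–Hochberg is
available behind a flag.

## Candidate funnel and validation statistics

A *carrier* holds one or two mutant alleles (het or hom-alt). The
funnel keeps sites with ≥`min_case_carriers` (3) case carriers,
≥`min_cross_carriers` (1) crossbreed carriers and
≤`max_control_carriers` (0) control carriers, then restricts to
HIGH/MODERATE impact (SnpEff-style classes, maximum severity across
transcripts). Missing genotypes never count as carriers and never count
against the control bound (configurable to "missing disqualifies");
"exclusively absent from controls" therefore means zero carriers among
called control genotypes. The two stages commute; the report simply
presents presence-before-impact. Interval-typed (structural) records go
through the same presence/absence screen without the impact stage,
optionally restricted to ±40 Mb windows around anchor SNPs.

Genotype-frequency tables use the total cohort size as denominator by
default (the convention of the published validation tables, which count
over 1275 straight- and 61 curly-haired animals), with a called-only
mode; display rounding is half-up to three decimals and raw fractions
are always retained. Dominance consistency declares a curly sample
concordant iff it carries ≥1 mutant allele at ≥1 candidate site and a
straight sample concordant iff it carries none; unknown phenotypes are
excluded with a logged count. The imputation error rate is the exact
genotype discordance on the sample×site intersection of two matrices,
excluding genotypes missing in either; per-SNP rates are averaged over
SNPs with at least one comparison. The measure is symmetric.

## Synthetic cohorts

The generator plants structure directly rather than simulating
genealogies — the analysis consumes genotypes, not coalescent history.
Per chromosome, SNP positions are drawn with exponential (WGS-like) or
uniform (chip-like) spacing; per-site allele frequencies come from a
symmetric Beta; controls draw Hardy–Weinberg genotypes. Case samples
receive an independent background (het with probability
`background_het_rate`, otherwise hom by allele frequency) and planted
homozygous tracts copied from a founder haplotype: `n_consensus_tracts`
identical in every case sample (of which `n_cross_shared_tracts` are
also planted in the crossbreeds), plus `n_planted_tracts` private
tracts per sample, placed without overlap and with a minimum gap.
F1 crossbreeds combine one case-derived and one control-derived allele
per site, so they are heterozygous wherever the pools are fixed for
different alleles and carry no long tracts outside the shared ones.
Breed-private variants (carriers: ≥3 random cases, ≥1 crossbreed, no
controls) are inserted with a configurable impact mix, plus decoys that
carry controls; the first private variant can act as a fully penetrant
dominant causal locus from which phenotypes are assigned. Missingness
and imputation-error injection happen last, with the pre-error matrix
retained. All outputs are deterministic functions of config + seed.

Key default choices, made once for the WGS-like configuration:

* **Scale**: 2 chromosomes × 20 Mb, cohorts 9 case / 3 crossbreed / 22
  control — the study design shrunk ~100-fold so the full chain runs in
  seconds to tens of seconds.
* **SNP density**: mean spacing 100 bp, matching the real density of a
  ~24 M-SNP panel over a 2.27-Gb autosome (~95 bp/SNP). The `wgs`
  density cap of 0.12 kb/SNP is only satisfiable at that density; a
  sparser grid would make every segment fail the density rule.
* **Background heterozygosity**: `background_het_rate=0.45` with
  Beta(5, 5) allele frequencies (common variants). This makes
  non-autozygous background essentially uncallable as ROH
  (P(window passes) ≈ 0.005), so planted truth is identifiable. This is
  a deliberate idealisation: real outbred genomes are less heterozygous
  at segregating sites and do show baseline ROH under these detector
  settings (published control breeds reach F_ROH 0.24–0.47). Passing
  truth-recovery tests therefore demonstrates correctness of the
  machinery, not that real-data consensus regions are noise-free.
* **Chip-like mode** uses uniform spacing (array designs target even
  coverage; exponential spacing at 50 kb mean would exceed the 100-kb
  gap rule ~14% of the time and shred tracts) and a light private-tract
  load so that 8-of-19 chance pileups of private autozygosity do not
  mimic consensus.

Other non-emulated features of real data: linkage disequilibrium,
recombination-driven tract length distributions, allele-frequency
ascertainment of array SNPs, genotyping error correlated with depth.

## Numerical and degenerate-input conventions

Hit rates are exact rational counts divided in double precision in both
the vectorised caller and the oracle, so their comparisons agree
bit-for-bit. Empty matrices, empty region lists and cohorts with no
called genotypes return empty/zero results rather than erroring;
division-undefined frequencies are NA in called-only mode. Tract
placement raises when the requested tracts cannot fit
(sum of lengths + gaps exceeds free space). Seeds derived from a master
seed stay below 2³¹.

## Known limitations

* The detector reproduces the sliding-window family of ROH callers;
  likelihood/HMM callers are out of scope and may disagree near
  segment boundaries.
* Consensus support is the minimum per-bp support, which equals the
  number of members covering the whole region only when the same
  members span it (the common case for kb-scale islands).
* The PED/MAP reader recodes against observed major/minor alleles, so
  hom-ref/hom-alt labels can swap relative to a reference-based coding
  when the alternative allele is the major one.
* The generator's idealised background (see above) means absolute
  false-positive rates of consensus detection on real data are not
  addressed by the test suite.
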