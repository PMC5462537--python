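# Methods

## The mapping model

A recessive lesion is mapped from an F2 incross of two heterozygous
carriers. Both carriers are modelled as F1 hybrids between the mutagenesis
background (which carries the lesion) and a polymorphic mapping background,
so every marker in the panel is heterozygous in both parents. Phenotyped
mutants are the homozygous quarter of the F2; pooling `n` of them samples
`2n` meioses around the lesion. At a marker at recombination fraction `r`
from the lesion the expected mutant-pool frequency of the lesion-linked
allele is `1 − r`; at unlinked markers it is 0.5. The wildtype-sibling pool
mixes the remaining genotype classes in their 1 (+/+) : 2 (+/−) segregation
proportions, giving an expected lesion-allele frequency of 1/3 — both
expectations are verified by seed-averaged simulation in the test suite.

Because the orientation of each marker (which allele rides the lesion
haplotype) is unknown in real data, the scan statistic is the **folded**
frequency `max(f, 1−f)`: 0.5 under free segregation, 1.0 at fixation,
regardless of allele labelling.

## Cross simulator

* **Meiosis.** Per gamete and chromosome, the crossover count is Poisson
  with mean equal to the genetic length in Morgans; breakpoints are uniform
  on the genetic map; no interference, no obligate chiasma. This is the
  simplest model with correct F2 marker expectations.
* **Genetic ↔ physical map.** Constant cM/Mb within each chromosome
  (configurable per chromosome through `Chromosome.genetic_length_cm`).
* **Pools.** Individuals are simulated until both pools fill: homozygous
  carriers go to the mutant pool, others to the sibling pool, which
  automatically realises the 1:2 sibling class ratio. With
  `phenotyping_error_rate > 0`, that fraction of mutant-pool slots is filled
  by misphenotyped siblings, capping the peak below 1.0.
* **Reads.** Depth per marker per pool is Poisson(`mean_depth`); alt reads
  are Binomial(depth, `q(1−e) + (1−q)e`) where `q` is the true pool allele
  frequency and `e` the symmetric sequencing error rate.
* **Expression.** Per-gene expected counts are lognormal across genes
  (meanlog 5, sdlog 1); counts are Poisson (optionally negative binomial via
  `expression_dispersion`). One planted gene — the gene nearest the lesion —
  has its baseline fixed at `planted_gene_mean` (500) and its mutant-pool
  mean multiplied by `expression_fold` (0.2).

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| pool sizes | 108 + 108 larvae | standard pooled-mapping design at this scale |
| genome | 25 chromosomes × 55 Mb × 100 cM | zebrafish-like karyotype and map length |
| markers | 200 per chromosome | transcriptome-scale informative SNP density |
| `mean_depth` | 50 reads/marker/pool | typical pooled RNA-seq coverage at kept sites |
| `seq_error_rate` | 0.005 | Illumina-scale per-base error |
| `phenotyping_error_rate` | 0 | clean phenotyping; exposed as a dial |
| causative locus | a marker in the central 60% of a random chromosome | lesions within half a window of a chromosome end are not localizable by a centered scan (see limitations) |

The simulator reproduces the *statistical* structure the analysis assumes —
segregation, linkage decay, pooled sampling noise — but not read-level
artifacts (alignment bias, allele-specific expression, duplicated regions,
variable marker density along real chromosomes). Passing recovery tests
therefore demonstrates correctness of the analysis under its own model, not
robustness to every artifact of real pooled RNA-seq.

## Marker discovery

Mapping markers are selected on wildtype-pool evidence only: biallelic SNV,
depth ≥ 20, alt fraction in [0.2, 0.8]. The exact thresholds are design
choices (published descriptions say only "high quality"); they are declared
in config, recorded in output headers, and an optional mutant-pool depth
floor is available but off by default. Filtering is idempotent and
monotone in the frequency window (property-tested).

## Sliding-window scan and interval call

Windows average the folded frequency over `w = 50` neighbouring loci
(marker count, not physical distance), never span chromosome boundaries,
and skip zero-depth markers. Windows are **centered**: for even `w`,
`(w−1)//2` markers left and `w//2` right; markers closer than that to a
chromosome end get no window value. Centered windows avoid the positional
bias of trailing windows; a `trailing` mode and averaging of raw rather
than folded frequencies are config-exposed since published descriptions do
not pin either choice down.

The peak is the global maximum of the window value; ties are broken by the
longest contiguous run of tied markers, then the lowest genomic coordinate.
The interval is the maximal contiguous run of windowed markers around the
peak with window value ≥ **0.98 × peak height** (relative mode, default).
An absolute-frequency mode exists, but a relative threshold is the default
because a centered 50-marker window spans many centimorgans at realistic
marker densities (200 markers over ~100 cM puts the window's expected mean
near 0.94 even directly over the lesion), so a fixed 0.98 cut would often
delimit an empty interval; the fraction-of-peak rule adapts to the marker
density and depth at hand. A flat profile (max − min < 0.01) is reported
as "no linkage" rather than a spurious interval.

Numerical notes: window means are exact sliding means (stride-tricks view,
oracle-tested against naive recomputation for `w ∈ {1,2,3,7,50}`); the run
expansion always contains the peak marker; all reported coordinates are
1-based inclusive, BED output 0-based half-open.

## Candidate triage

Variant effects are computed against single-transcript gene models
(GFF3 + FASTA, or simulated models): genomic position → spliced CDS
coordinate (strand-aware), codon substitution, translation with the
standard nuclear code. Classes: synonymous, missense, nonsense, stop-loss,
frameshift (indel length mod 3 ≠ 0 in CDS), in-frame indel, splice-site
(intronic within 2 bp of an exon edge, or a junction-spanning deletion),
noncoding. Start-codon loss is recorded in a note and ranked with missense
severity. Indels are left-aligned against the contig sequence when one is
available. The ref allele is checked against the reference at CDS
positions; a mismatch is a data-integrity error naming the locus. Severity
ranking (nonsense < frameshift < stop-loss < missense < in-frame indel <
splice-site < synonymous < noncoding) is total and deterministic; ties are
broken by coordinate.

The expression screen tests each interval gene's mutant count against its
expectation under equal expression with a two-sided binomial test
(success probability = mutant library share of the pooled total),
BH-adjusts across tested genes, and flags genes with normalized fold
change ≤ 0.5 and adjusted p ≤ 0.05, reduced direction only. The binomial
test on pooled counts is a deliberate, swappable simplification; it
ignores biological replication (there are two pools, not replicates), so
its p-values calibrate sampling noise only.

## Known limitations

* Lesions within half a window of a chromosome end produce no window value
  at their position and cannot be localized precisely; the simulator's
  default lesion placement avoids the outer 20% of the chromosome, and
  real scans should treat terminal regions with caution.
* Single transcript per gene; no isoform resolution, no protein-impact
  scoring.
* The interval width scales with marker density and window size; at the
  default simulated density (~0.5 cM marker spacing) intervals are several
  Mb, wider than what denser real marker sets can achieve.
* No confidence intervals on the peak (bootstrap/QTL-seq style CIs are an
  extension hook, not implemented).

## Problem sizes used in the test suite

Recovery experiments run 50 full-scale crosses (25 × 200 markers, 108+108
larvae); segregation expectations average 200 seeds on a 2-chromosome
genome; oracle-equivalence checks sweep 100 random profiles and all
64 × 9 codon substitutions. These sizes give Monte-Carlo standard errors
comfortably below the tested tolerances while keeping the whole suite fast.
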