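# Methods

## The locus model

All analyses run against a `GeneModel`: named exon intervals (1-based
inclusive) on one chromosome with a strand. The default synthetic locus
(`build_toy_locus`) places, on the minus strand of a 12-kb chromosome,
e21 at 1,001–1,200, the cryptic exons CE128 at 3,001–3,128 and CE178 at
3,001–3,178, e20 at 5,001–5,150 and e19 at 7,001–7,200. This reproduces
the real geometry at toy scale: the two CE forms share the transcript 3′
end (the lower genomic coordinate on the minus strand), CE178 is 50 bases
longer at the 5′ end, and both sit in the intron between exons 20 and 21.
Toy-scale coordinates keep simulation and tests fast and download-free;
the genuine GRCh38 CE coordinates appear only in documentation and in the
acceptance worked examples, where their inclusive lengths (128, 178, Δ50)
are recomputed.

Junctions are represented by the genomic interval of the skipped intron.
The named junctions follow from exon adjacency: e19–e20, e20–CE128,
e20–CE178, the single shared CE–e21 (both CE forms splice to e21 from the
same boundary) and the exclusion junction e20–e21. Classification demands
an exact interval match — the analysis counts reads at specific annotated
junctions, so no fuzz window is applied; near-miss junctions are tallied
as `unclassified`.

The locus also carries an exonic SNP inside CE128 (dbSNP-style forward
alleles C>G at 3,050), an intronic SNP (A>C at 4,500) and a CATC-repeat
site (6 baseline units at 4,000). Alleles are stored forward-strand
everywhere, matching VCF/dbSNP convention; `strand_convert` produces the
gene-strand representation (G↔C, CATC↔GATG for a minus-strand gene).

## Read simulation

`simulate_rnaseq_sample` draws single-end reads (default 100 nt, one of
M/N/S CIGAR ops, at most one gap per read at default geometry) from the
three-isoform mixture {canonical : CE128 : CE178} with proportions
{1−ψ, ψ(1−s), ψs}, where ψ = `psi_true` and s = `ce178_share`
(default 0.1 — the 128-bp form dominates in observed data; the true ratio
is a free parameter, not an estimate). Isoforms are sampled with
probability proportional to mixture weight × effective length and read
starts uniformly within the isoform, as fragment sampling in RNA-seq
does; this makes the expected read count at every junction proportional
to its isoform's molar abundance, so the junction PSI estimator is
unbiased. `depth` parameterizes the *expected junction-informative read
count* (reads spanning some junction with ≥ 6-nt overhangs); the total
emitted read count is scaled accordingly.

Artifact structure mirrors the output contracts of the standard
preprocessing tools rather than re-deriving them: PCR duplicates are
emitted as extra copies carrying the SAM 0x400 flag (the contract of
duplicate marking), and non-unique mappers carry a sub-unique MAPQ
(default 3 versus the unique value 255). Per-base substitution errors and
an optional `unspliced_rate` (pre-mRNA reads, producing intron-body
alignments) complete the model. There is no base-quality, fragment-length
or indel-error model, and no FASTQ/alignment step: passing tests
demonstrate the counting and calling logic, not robustness to alignment
artifacts.

Sampling truth is recorded per sample (realized per-junction counts among
filter-passing reads, ψ). All generators take a seed and use NumPy's
PCG64; identical parameters and seed give byte-identical SAM/VCF/TSV.

## Quantification and calling

Reads are filtered (duplicate flag, MAPQ ≥ 255 by default), gaps with
≥ 6 aligned bases on each side become junctions (the minimum-overhang rule
used by junction-based splicing tools; configurable, applied uniformly),
and each read contributes at most once per named junction — a long read
spanning e20–CE and CE–e21 increments both, since counting is per
junction. Deletions (D) extend an aligned block rather than opening a
junction; only N does.

The sample-suitability gate admits samples with naive TPM ≥ 1.55 **or**
≥ 20 e19–e20 junction reads (inclusive thresholds); the naive TPM is
(exon-overlapping reads / model exonic kb) / (library reads / 10⁶),
a deliberately simple stand-in for a full transcript-abundance estimate,
adequate because the gate only needs a monotone expression proxy. A
suitable sample is CE-positive with ≥ 2 reads over the *union* of the CE
junctions — the plain-language reading of "at least 2 reads spanning
either junction", and the more sensitive detection floor; a
`strict_per_junction` mode requiring the threshold at a single junction
class is provided since the alternative reading cannot be excluded.

Two inclusion statistics are computed:

- **inclusion fraction** — CE-supporting reads (the three CE junctions
  plus reads aligned wholly within the CE178 footprint) over
  CE-supporting + e20–e21 reads. Unspliced intron-body reads support
  neither isoform and are tallied separately rather than placed in the
  denominator, which would make the statistic depth- and
  intron-length-dependent. This is a documented interpretation: a
  denominator of *all* intron-mapped reads is defensible too, and the
  tally needed to compute it is retained (`intron_body_reads`).
- **junction PSI** — Ψ = m/(m + x) with m the mean of the two inclusion
  junction counts (upstream e20–CE128+e20–CE178, downstream CE–e21) and
  x the e20–e21 count. Averaging the inclusion junctions is standard
  junction-PSI practice and avoids double-counting reads spanning both.

Cohort summaries report CE-positive fractions among suitable samples per
group. The coverage QC is the Pearson correlation of e19–e20 versus
e20–e21 counts across samples; it approaches 1 when between-sample
expression variability dominates (as in real cohorts, emulated with
log-uniform depths in the acceptance script) and is undefined under zero
variance.

## Allelic imbalance

Amplicon reads spanning e19→e21 are classified by their junction chain
(canonical, CE128, CE178, otherwise "other") and CE-class reads are
partitioned by the base carried at the CE SNP. Bases matching neither
allele are counted as "other" and excluded from the percentage — the
neutral choice for sequencing errors. Per sample the pair
(risk %, reference %) is formed and the paired two-sided t-test is run on
d = risk% − ref% with df = n−1; a per-sample exact binomial test against
0.5 is provided as a secondary check. The generator gives CE reads the
risk allele with probability OR/(OR+1) in a heterozygote, so OR = 1 is
the exact symmetric null and OR = 3 yields a 75 % risk share. For
replicate studies (calibration/power), `simulate_allele_tallies` draws
the tally counts directly from the same Binomial mechanism without
materialising reads.

## Genotypes, LD and dose association

`simulate_genotype_cohort` draws a latent risk/reference state per
haplotype at the risk-haplotype frequency; each marker (two SNPs and the
repeat class) copies that state with probability `r2_link**0.25` and
otherwise re-draws from the population frequency. Two markers then
correlate through the shared latent state with r² ≈ `r2_link`, with exact
behaviour at both ends (r²=1: identical doses; r²=0: independence).
Risk-state haplotypes carry 3–5 additional CATC units, reference
haplotypes 0–2, around a 6-unit baseline — the separation reported for
risk- versus reference-homozygous patients. The VCF writer emits the
repeat as one multi-allelic indel record (anchor base + k motif copies).

The LD statistic is the genotype-independence chi-square: individuals
cross-tabulated by unphased genotype class at two loci (allele counts
bounded to [2, 8] when scanning multi-allelic sites),
χ² = Σ(O−E)²/E over cells with E > 0, df = (r−1)(c−1) over observed
non-empty classes, upper-tail p. No continuity correction and no cell
pooling, so results are exactly reproducible from the table; for sparse
tables this df convention can differ from implementations that pool.

Repeat dosage scores an ALT allele as (len(alt)−len(ref))/len(motif)
additional units when the allele is the reference with a contiguous exact
motif tandem inserted, else flags it non-conforming. Haplotype dose is
the shared risk-allele count when the two tag SNPs agree; discordant or
missing genotypes are excluded with a recorded reason — concordance is
the evidence that an unphased individual carries intact haplotypes.

The dose–abundance association is OLS (via statsmodels) of abundance on
additively coded dose, optional covariate columns after the dose (the
covariate set of the original model is unspecified, so the default model
is abundance ~ dose). A rank-deficient design raises; an exact fit
returns coefficients with a zero-residual flag and no inference. ΔΔCt
clamps Ct values above 40 cycles to 40 before differencing, and Spearman
uses average ranks with an undefined-value flag under zero rank variance.

## Problem sizes and numerical choices

The test suite and acceptance script run at sizes chosen to give stable
statistics on a laptop-class machine: 20 samples for the brute-force
counting oracle, 40 samples at ~2,200 junction-informative reads for PSI
recovery (mean |Ψ̂−ψ| ≈ 0.008, comfortably under the 0.02 design
tolerance), 100 null + 60 low-PSI samples for specificity/sensitivity,
500 triplicates for null calibration (KS against uniform at α = 0.01) and
200 for power, 1,000 cohorts of 500 for chi-square type-I error, and 500
replicates of n = 85 for the 95 % CI coverage of the dose slope
(β₁ = 0.175, σ = 0.3).

Floating-point policy: thresholds are inclusive (≥) per their "at least"
definitions; undefined statistics (zero denominators, zero variance)
return flagged `None` values rather than raising, except where a test is
mathematically undefined (paired test with zero-variance differences,
chi-square with a single genotype class), which raises.

## Known limitations

- The simulator emulates junction-count statistics, not sequence realism:
  no quality model, no alignment step, no splice-site motifs. Conclusions
  about aligner- or library-induced biases are out of scope.
- The naive TPM is not a transcript-abundance estimate; it only feeds the
  suitability gate.
- The LD generator's r² is an expectation under the latent-state model,
  not a per-cohort guarantee, and haplotypes are drawn independently
  (no population structure, no recombination map).
- Junction classification is exact-match by design; reads from unannotated
  splice variants appear only in the `unclassified` tally.
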