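# Methods

This note documents the models, defaults and numerical choices behind
`strainvar`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Data model

Variants are bi-allelic records (chrom, 1-based pos, ref, alt) with alleles
restricted to A/C/G/T; multi-allelic VCF records are split into one site
per ALT at read time, because all downstream logic (spectrum classes,
codon substitution, 0/1 genotype vectors) is per-substitution. Genotypes
are coded REF_HOM / ALT_HOM / HET / MISSING; phasing is ignored. Because
inbred strains are expected to be homozygous, any site with a heterozygous
call in any sample is split off whole (`partition_zygosity`) before
analysis — heterozygosity in this setting mostly reflects incomplete
fixation, collapsed duplications or technical error, and removing the whole
site rather than the single call keeps all samples comparable at every
retained site. All internal coordinates are 1-based inclusive; BED-like
inputs are converted at the file boundary.

## Truth-set validation and extrapolation

`tally_concordance` matches truth and test calls by exact (chrom, pos, ref,
alt) identity after normalization, restricted to merged truth regions.
Indels use the same exact-identity rule after left-alignment; no fuzzy
position window is applied, which keeps the tally deterministic at the cost
of counting representation differences as errors. Extrapolation assumes the
truth regions are representative of the genome:

    est_missed = round(total_called * FN / TP)
    pct_missed = 100 * FN / (TP + FN)
    est_fp     = round(total_called * FP / TP)
    pct_fp     = 100 * FP / (TP + FP)

Counts round half-up; percentages are reported to one decimal. The FP count
uses the FN-symmetric formula; the FP *percentage* is the better-anchored
quantity and the one to quote.

## Effect annotation

Categories follow the classic SnpEff-style taxonomy with impact tiers
HIGH (stop gained/lost, start lost, splice donor/acceptor), MODERATE
(non-synonymous coding), LOW (synonymous coding, synonymous stop,
start gained, non-synonymous start) and MODIFIER (UTRs, intron, exon of a
non-coding transcript, 5 kb upstream/downstream, intergenic). Choices the
taxonomy leaves open:

- Splice sites are the first/last 2 intronic bases, strand-aware.
- The upstream/downstream span is fixed at 5 kb (the common annotator
  convention).
- A start-codon SNV that produces an alternative initiation codon
  (CTG/GTG/TTG) is `non_synonymous_start` (LOW); any other start change is
  `start_lost` (HIGH).
- `start_gained` is a 5'-UTR SNV that creates a new ATG covering the
  variant position; it is LOW impact.
- Standard nuclear genetic code only; translation via Biopython.
- The per-site summary is the maximum-impact annotation across overlapping
  transcripts.

## ORF restoration

"Neighboring variants" are operationalized as *all* of a strain's variants
within the focal transcript, applied jointly — haplotype-consistent and
parameter-free (inbred strains are effectively haploid, so all calls are in
cis). The transcript is considered disrupted when any of: premature stop in
the translation, first codon not an initiation codon, missing terminal
stop, net coding-sequence length not a multiple of 3, or a non-canonical
GT..AG intron dinucleotide. A focal HIGH-impact variant is *restored* when
it disrupts the transcript alone but the joint haplotype shows no
disruption. The check is order-independent and idempotent in the variant
list. Variants that only partially overlap a CDS edge are treated as
unresolved disruptions rather than silently clipped.

## Ka/Ks

The per-gene ratio is the raw nonsynonymous/synonymous *count* ratio over
coding SNVs; nonsense and start-disrupting changes count as nonsynonymous,
synonymous-stop as synonymous. A Nei-Gojobori-style site-normalized mode
(`site_normalized_ratio`) is available but not the default, because the
count ratio is what the upstream gene-selection rule (>= 6 coding SNVs,
ratio > 1.0 strict) is defined on. Zero synonymous counts give an infinite
ratio; genes with no coding SNVs have an undefined (None) ratio and are
never selected.

## Expression and exon usage

FPKM = count * 1e9 / (length_nt * library_size). PSI normalizes inclusion
reads by the number of read start positions overlapping the exon
(`exon_length + read_length - 1`) so they are comparable to
single-position junction (exclusion) counts:

    psi = inc_norm / (inc_norm + exclusion),  inc_norm = inc * RL / (L + RL - 1)

with PSI = 0 when the exon has no reads at all (unused exon) and PSI = 1
when there are inclusion reads and no exclusion reads (constitutive exon).
This normalization constant is a design choice: it is the standard way to
put per-base and per-junction counts on one scale, but published PSI values
computed with a different constant will differ numerically while ordering
exons the same way.

Set-vs-background comparisons use the Wilcoxon rank-sum test (exact for
group sizes <= 20, normal approximation with tie correction otherwise);
a Kruskal-Wallis mode covers more than two groups. Background exon sets are
uniform samples without replacement from exons of expressed genes
(mean FPKM >= 1), reproducible under a seed; the default background size is
16,000.

## Cross-species density windows

Windows are anchored every 25 kb on the common coordinate frame and extend
until they contain 100 kb of the species' syntenic sequence, so windows
lengthen across synteny gaps and are omitted where a chromosome runs out of
syntenic blocks. Per-species SNV counts are z-scored across windows
(z = 0 when the counts are constant), which makes species with very
different absolute diversity comparable. Shared extreme loci keep windows
where *every* species falls inside its own lower (or upper)
10th-percentile tail — nearest-rank percentiles, which keep boundary ties —
and merge kept windows that overlap or touch. Because the percentile cut is
a monotone transform, cutting on z-scores or raw counts selects identical
windows.

## Cluster-mosaic assignment

The genome is divided into consecutive blocks of 20,000 SNVs (never
spanning chromosomes; the last block per chromosome may be smaller). Per
window, each cluster's profile is the per-site fraction of ALT-homozygous
member strains (missing calls excluded). A strain's 0/1 vector is compared
to each profile by Spearman rank correlation with midrank ties, excluding
missing calls pairwise; the window is assigned to the cluster with the
maximum coefficient, exact ties going to the lexicographically first
cluster with a tie flag. Assignment is withheld below 10 informative sites
or when every correlation is undefined (constant vectors). Cluster
*membership* is an input table — the model fitting that produces it
(e.g. variational admixture inference) is upstream and out of scope; the
synthetic generator supplies memberships from its planted truth.

## Substrain analysis

A site is "variable between substrains" of a group when all members are
called (MISSING disqualifies the site — the conservative reading, since an
uncalled member could hide concordance) and at least two distinct
homozygous genotypes occur. The control set for spectrum/conservation/KaKs
contrasts is all sites minus those ALT-homozygous in every sample minus all
substrain-variable sites.

The mutational spectrum collapses each SNV to the pyrimidine reference
strand (7 classes; C>T split by CpG context, read from the reference
sequence only — strain-specific context is not reconstructed). Class
comparisons against the control set use a two-sided exact binomial test of
the observed class count against the control proportion at n = observed
total, Bonferroni-corrected across the 7 classes (a deliberate conservative
choice; the uncorrected mode is a flag). The 95% CI on the expected count
is a normal-approximation binomial interval by default, Clopper-Pearson by
flag. An empty control class with nonzero observations is tested against a
floor proportion of 0.5/control_total with a warning.

Conservation contrasts use Welch's unequal-variance t-test on per-base
scores at variant positions; sites without a score are skipped and counted.
Welch is preferred over the pooled-variance t-test because the two variant
sets differ in size by orders of magnitude.

## Synthetic data

The default `PopulationScenario` is shaped like the 40-strain panel the
pipeline was built around: 9 ancestral clusters, two strains per cluster,
seven strains carrying 2-4 sequenced substrains (these form the
substrain-variability groups), a 2 Mb single-chromosome genome with 50,000
ancestral SNVs (each private to one cluster and shared by all its samples),
500 drift SNVs per substrain, a site-level heterozygous-noise rate of 2.5%
(matching the homozygosity of the published call set) and 0.2% missing
calls. The drift spectrum is CpG-deamination-dominated (C>T = 0.49 split
0.28 CpG / 0.21 non-CpG, T>C = 0.21), qualitatively matching the observed
excess of C>T at CpG and the below-control share of T>C among substrain
variants. Drift SNVs are placed only at positions monomorphic in the
ancestral population with a reference context matching their class (CpG
classes at CpG sites), which makes them substrain-private by construction.
Noise is injected only at ancestral sites so every truth record corresponds
to an emitted record. Planted mosaic switches copy a source cluster's
ancestral genotypes into a target cluster within one fixed-count window.

One integer seed fans out through per-generator independent streams
(SeedSequence keyed by seed and a CRC of the generator name), so adding a
generator never changes another's output and equal seeds give byte-identical
files.

What the generator does *not* emulate: linkage/recombination structure,
coalescent genealogies, read-level error (no FASTQ), indel-rich regions,
reference assembly artifacts, and realistic gene density or codon usage.
Recovery tests on this output therefore demonstrate the correctness of the
bookkeeping and the calibration of the statistics under the stated model —
not the behavior of the pipeline on the idiosyncrasies of real sequencing
data.

## Problem sizes in the test suite

Simulation-backed tests run on scaled-down inputs chosen to keep the suite
fast while leaving enough statistical power for the planted effects:
genomes of 0.1-2 Mb, 1,000-50,000 ancestral SNVs, 5,000 drift SNVs per
spectrum-recovery replicate over 20 seeds, 200 null replicates for test
calibration, and 150-200 genes for expression and ORF-restoration checks.
The acceptance script (`scripts/acceptance.py`) runs the full default
2 Mb scenario once.

## Known limitations

- Indel effect annotation is coarse (region-level categories only); codon
  logic applies to SNVs.
- Exact-identity indel concordance will undercount matches for equivalent
  but differently normalized representations.
- The ORF-restoration haplotype rebuild handles deletions spanning a CDS
  boundary conservatively (flagged as disrupted, not resolved).
- `compare_spectra` treats classes independently; a compositional test
  (e.g. chi-square over all 7 classes) is not provided.
- The cluster-mosaic profile includes the query strain itself when the
  membership table says so, diluting profiles in small clusters; supplying
  leave-one-out memberships is the caller's choice.
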