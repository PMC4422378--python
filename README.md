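# strainvar

Downstream analysis of genomic variation among inbred rat strains and
substrains: a reusable Python implementation of the analysis layer that
turns a uniformly called multi-strain variant set into the quantities a
strain-genomics study reports.

Inbred strains are (nearly) fully homozygous, so a multi-sample call set
reduces to a samples x sites matrix of 0/1 genotypes. On that matrix the
package answers questions such as:

- **How good are the calls?** Concordance against a finished-sequence truth
  region (e.g. capillary-sequenced BAC clones) gives TP/FN/FP tallies, which
  extrapolate to genome-wide error counts:
  `est_missed = total_called * FN / TP` and miss rate `FN / (TP + FN)`.
- **Do "high impact" variants matter?** A stop-gain or splice-site SNV
  annotated in isolation may be neutralized by a neighboring variant on the
  same haplotype. `check_orf_restoration` re-translates the transcript with
  all of a strain's variants applied jointly. Genes and exons carrying
  high-impact SNVs are compared against background expression (FPKM) and
  exon usage (PSI) by Wilcoxon rank-sum tests.
- **Which genes are under selection?** Per-gene nonsynonymous/synonymous
  SNV count ratios (Ka/Ks); genes with >= 6 coding SNVs and ratio > 1 are
  candidates for positive selection.
- **Where do strains share ancestry?** The genome is cut into windows of
  20,000 SNVs; each strain's 0/1 vector is Spearman-correlated with the
  mean genotype profile of each ancestral cluster and the window is
  assigned to the argmax — the "cluster mosaic" of shared haplotypes.
- **What distinguishes substrains?** Within each strain group, sites where
  substrains disagree are the variants that arose after colony separation.
  Their spacing exposes introgressed segments; their pyrimidine-collapsed
  mutational spectrum (with C>T split by CpG context) is compared
  class-by-class against a control SNV set with exact binomial tests; and
  their conservation (phastCons) scores are contrasted by Welch's t-test.

A seeded synthetic-data module (`strainvar.synthetic`) generates every
input the pipeline consumes — reference FASTA, multi-sample VCF with
planted cluster structure and substrain drift, gene models with plantable
rescued/unrescued high-impact variants, expression counts with a planted
repression effect, degraded call sets with known FN/FP rates, and
conservation tracks — together with a truth bundle so every analysis can be
validated by recovery of what was planted.

## Worked example

Error extrapolation from a truth region (13 finished BAC clones,
2,132,438 nt evaluated; 2,468 concordant SNVs, 141 missed, 14 spurious)
to a genome-wide set of 9,183,702 SNV calls:

```python
from strainvar.validation import (
    ConcordanceCounts, extrapolate_genomewide, concordance_report,
)

c = ConcordanceCounts(evaluated_nt=2_132_438, tp=2_468, fn=141, fp=14)
est = extrapolate_genomewide(c, total_called=9_183_702)
print(concordance_report(c, est))
```

prints

```
Evaluated 2,132,438 nt (SNV)
  concordant (TP): 2,468
  missed (FN):     141
  spurious (FP):   14
Genome-wide extrapolation:
  estimated missed calls: 524,677 (5.4%)
  estimated false calls:  52,096 (0.6%)
```

i.e. roughly 5.4% of true SNVs are estimated to be missing from the
genome-wide call set and 0.6% of calls are estimated to be spurious.

A full synthetic input bundle, with planted ground truth, in one command:

```bash
strainvar simulate --out sim/ --seed 1
strainvar substrain --vcf sim/variants.vcf --groups sim/groups.tsv \
    --ref sim/reference.fa
```

The second command reports per-group substrain SNV counts with a total row
and the observed-vs-expected substitution spectrum of the discovered
substrain variants.

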