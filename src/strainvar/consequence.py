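"""Variant-effect annotation, ORF-restoration checking and Ka/Ks counting.

Effect categories follow the classic SnpEff-style taxonomy with four impact
tiers.  Disruptive consequences (stop gain/loss, start loss, splice-site
disruption) are HIGH impact; amino-acid changes are MODERATE; synonymous and
start-adjacent changes are LOW; everything non-coding is MODIFIER.

A HIGH-impact call made on one variant in isolation can be a false alarm:
a second variant on the same inbred haplotype may restore the reading frame
(e.g. a second substitution in the same codon turning a premature stop back
into a sense codon).  :func:`check_orf_restoration` re-evaluates the
transcript with all of a strain's variants applied jointly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .variant_io import VariantSite

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# alternative initiation codons tolerated by the scanning machinery;
# a start codon mutated into one of these is LOW, not HIGH
_ALT_STARTS = {"CTG", "GTG", "TTG"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding sequence (standard nuclear code, '*' for stop)."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


class Impact(enum.IntEnum):
    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


class EffectCategory(str, enum.Enum):
    stop_gained = "stop_gained"
    splice_site_donor = "splice_site_donor"
    splice_site_acceptor = "splice_site_acceptor"
    start_lost = "start_lost"
    stop_lost = "stop_lost"
    non_synonymous_coding = "non_synonymous_coding"
    synonymous_coding = "synonymous_coding"
    start_gained = "start_gained"
    synonymous_stop = "synonymous_stop"
    non_synonymous_start = "non_synonymous_start"
    exon = "exon"
    utr_5 = "utr_5"
    utr_3 = "utr_3"
    intron = "intron"
    upstream = "upstream"
    downstream = "downstream"
    intergenic = "intergenic"


IMPACT_OF: dict[EffectCategory, Impact] = {
    EffectCategory.stop_gained: Impact.HIGH,
    EffectCategory.splice_site_donor: Impact.HIGH,
    EffectCategory.splice_site_acceptor: Impact.HIGH,
    EffectCategory.start_lost: Impact.HIGH,
    EffectCategory.stop_lost: Impact.HIGH,
    EffectCategory.non_synonymous_coding: Impact.MODERATE,
    EffectCategory.synonymous_coding: Impact.LOW,
    EffectCategory.start_gained: Impact.LOW,
    EffectCategory.synonymous_stop: Impact.LOW,
    EffectCategory.non_synonymous_start: Impact.LOW,
    EffectCategory.exon: Impact.MODIFIER,
    EffectCategory.utr_5: Impact.MODIFIER,
    EffectCategory.utr_3: Impact.MODIFIER,
    EffectCategory.intron: Impact.MODIFIER,
    EffectCategory.upstream: Impact.MODIFIER,
    EffectCategory.downstream: Impact.MODIFIER,
    EffectCategory.intergenic: Impact.MODIFIER,
}

FLANK_BP = 5_000  # upstream/downstream annotation span


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a protein-coding (or non-coding) gene.

    Intervals are 1-based inclusive, sorted, non-overlapping; ``cds``
    intervals lie within ``exons``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("exons", "cds"):
            ivs = getattr(self, name)
            object.__setattr__(self, name, tuple(tuple(iv) for iv in ivs))
            ivs = getattr(self, name)
            if list(ivs) != sorted(ivs):
                raise ValueError(f"{name} must be sorted")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals overlap")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError("cds interval not contained in an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


@dataclass(frozen=True)
class EffectAnnotation:
    site: VariantSite
    category: EffectCategory
    gene_id: str | None = None
    transcript_id: str | None = None

    @property
    def impact(self) -> Impact:
        return IMPACT_OF[self.category]


@dataclass(frozen=True)
class GeneSelectionStats:
    """Per-gene synonymous/nonsynonymous tallies for selection scanning."""

    gene_id: str
    n_nonsyn: int
    n_syn: int

    @property
    def n_coding_snvs(self) -> int:
        return self.n_nonsyn + self.n_syn

    @property
    def ratio(self) -> float | None:
        """Nonsyn/syn count ratio; inf when syn = 0; None when no coding SNVs."""
        if self.n_coding_snvs == 0:
            return None
        if self.n_syn == 0:
            return float("inf")
        return self.n_nonsyn / self.n_syn


# ---------------------------------------------------------------------------
# Reference sequence access: plain dict of strings or pyfaidx.Fasta
# ---------------------------------------------------------------------------

def fetch(ref, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of the reference, uppercased."""
    seq = ref[chrom]
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()  # pyfaidx FastaRecord


def _check_ref(site: VariantSite, ref) -> None:
    obs = fetch(ref, site.chrom, site.pos, site.pos + len(site.ref) - 1)
    if obs != site.ref:
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"expected {site.ref!r}, reference has {obs!r}"
        )


# ---------------------------------------------------------------------------
# Coordinate helpers on the coding strand
# ---------------------------------------------------------------------------

def _spliced(intervals: Sequence[tuple[int, int]], chrom: str, strand: str, ref) -> str:
    seq = "".join(fetch(ref, chrom, s, e) for s, e in intervals)
    return revcomp(seq) if strand == "-" else seq


def coding_sequence(model: GeneModel, ref) -> str:
    """Spliced CDS on the coding strand (starts at the initiation codon)."""
    return _spliced(model.cds, model.chrom, model.strand, ref)


def _to_block_coord(
    intervals: Sequence[tuple[int, int]], strand: str, pos: int
) -> int | None:
    """0-based position of ``pos`` within spliced, stranded intervals."""
    offset = 0
    total = sum(e - s + 1 for s, e in intervals)
    for s, e in intervals:
        if s <= pos <= e:
            plus = offset + (pos - s)
            return plus if strand == "+" else total - 1 - plus
        offset += e - s + 1
    return None


def _classify_codon_change(cds: str, cpos: int, alt_base: str) -> EffectCategory:
    codon_i, within = divmod(cpos, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        raise _IncompleteCodon(cpos)
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = translate(codon)
    alt_aa = translate(alt_codon)
    if codon_i == 0:
        return (
            EffectCategory.non_synonymous_start
            if alt_codon in _ALT_STARTS
            else EffectCategory.start_lost
        )
    if ref_aa == "*":
        return (
            EffectCategory.synonymous_stop
            if alt_aa == "*"
            else EffectCategory.stop_lost
        )
    if alt_aa == "*":
        return EffectCategory.stop_gained
    if ref_aa == alt_aa:
        return EffectCategory.synonymous_coding
    return EffectCategory.non_synonymous_coding


class _IncompleteCodon(Exception):
    pass


def _splice_category(
    model: GeneModel, pos: int
) -> EffectCategory | None:
    """Donor/acceptor if pos is in the first/last 2 bases of an intron."""
    for s, e in model.introns():
        if not s <= pos <= e:
            continue
        at_left = pos - s < 2
        at_right = e - pos < 2
        if not (at_left or at_right):
            return EffectCategory.intron
        donor_side = at_left if model.strand == "+" else at_right
        return (
            EffectCategory.splice_site_donor
            if donor_side
            else EffectCategory.splice_site_acceptor
        )
    return None


def _utr_category(model: GeneModel, site: VariantSite, ref) -> EffectCategory:
    """5'/3' UTR, upgrading a 5'-UTR SNV that creates an ATG to start_gained."""
    tpos = _to_block_coord(model.exons, model.strand, site.pos)
    cds_start_genomic = (
        model.cds[0][0] if model.strand == "+" else model.cds[-1][1]
    )
    cds_start_t = _to_block_coord(model.exons, model.strand, cds_start_genomic)
    assert tpos is not None and cds_start_t is not None
    if tpos >= cds_start_t:
        return EffectCategory.utr_3
    if site.is_snv:
        tx = _spliced(model.exons, model.chrom, model.strand, ref)
        alt = site.alt if model.strand == "+" else revcomp(site.alt)
        mutant = tx[:tpos] + alt + tx[tpos + 1 :]
        for w in range(max(0, tpos - 2), tpos + 1):
            if mutant[w : w + 3] == "ATG" and tx[w : w + 3] != "ATG":
                return EffectCategory.start_gained
    return EffectCategory.utr_5


def annotate_effect(
    site: VariantSite, models: Iterable[GeneModel], ref
) -> list[EffectAnnotation]:
    """Annotate one variant against every overlapping transcript.

    Returns one annotation per transcript whose span (plus 5 kb flanks)
    contains the site, or a single intergenic annotation if none does.
    Coding categories are resolved by substituting the allele into the
    affected codon; only SNVs get codon-level categories.
    """
    _check_ref(site, ref)
    out: list[EffectAnnotation] = []
    for model in models:
        if model.chrom != site.chrom:
            continue
        ann = _annotate_one(site, model, ref)
        if ann is not None:
            out.append(ann)
    if not out:
        out.append(EffectAnnotation(site, EffectCategory.intergenic))
    return out


def _annotate_one(site: VariantSite, model: GeneModel, ref) -> EffectAnnotation | None:
    pos = site.pos

    def mk(cat: EffectCategory) -> EffectAnnotation:
        return EffectAnnotation(site, cat, model.gene_id, model.transcript_id)

    if model.start <= pos <= model.end:
        cpos = _to_block_coord(model.cds, model.strand, pos) if model.cds else None
        if cpos is not None:
            if not site.is_snv:
                return mk(EffectCategory.exon)
            cds = coding_sequence(model, ref)
            alt = site.alt if model.strand == "+" else revcomp(site.alt)
            try:
                return mk(_classify_codon_change(cds, cpos, alt))
            except _IncompleteCodon:
                warnings.warn(
                    f"incomplete terminal codon in {model.transcript_id}; "
                    f"site {site.chrom}:{site.pos} left uncategorized",
                    stacklevel=3,
                )
                return mk(EffectCategory.exon)
        in_exon = any(s <= pos <= e for s, e in model.exons)
        if in_exon:
            if not model.is_coding:
                return mk(EffectCategory.exon)
            return mk(_utr_category(model, site, ref))
        cat = _splice_category(model, pos)
        return mk(cat if cat is not None else EffectCategory.intron)

    if model.start - FLANK_BP <= pos < model.start:
        before = True
    elif model.end < pos <= model.end + FLANK_BP:
        before = False
    else:
        return None
    upstream_side = before if model.strand == "+" else not before
    return mk(
        EffectCategory.upstream if upstream_side else EffectCategory.downstream
    )


def worst_effect(annotations: Sequence[EffectAnnotation]) -> EffectAnnotation:
    """Summary annotation: the maximum-impact consequence across transcripts."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    return max(annotations, key=lambda a: (a.impact, a.category.value))


# ---------------------------------------------------------------------------
# ORF restoration
# ---------------------------------------------------------------------------

def _apply_to_block(
    intervals: Sequence[tuple[int, int]],
    strand: str,
    chrom: str,
    ref,
    variants: Sequence[VariantSite],
) -> str | None:
    """Spliced stranded sequence with variants applied; None if a variant
    only partially overlaps the blocks (unsupported edge case)."""
    seq = _spliced(intervals, chrom, strand, ref)
    edits: list[tuple[int, int, str]] = []  # (block_pos, ref_len, replacement)
    for v in variants:
        if v.chrom != chrom:
            continue
        positions = [
            _to_block_coord(intervals, strand, v.pos + i) for i in range(len(v.ref))
        ]
        if all(p is None for p in positions):
            continue
        if any(p is None for p in positions):
            return None  # straddles a block edge
        if strand == "+":
            edits.append((positions[0], len(v.ref), v.alt))
        else:
            edits.append((min(positions), len(v.ref), revcomp(v.alt)))
    for bpos, rlen, repl in sorted(edits, reverse=True):
        seq = seq[:bpos] + repl + seq[bpos + rlen :]
    return seq


def _high_impact_defects(
    model: GeneModel, ref, variants: Sequence[VariantSite]
) -> set[str]:
    """Disruptions of the transcript after applying ``variants`` jointly."""
    defects: set[str] = set()

    # splice dinucleotides (GT..AG on the coding strand of each intron)
    for s, e in model.introns():
        intron_vars = [v for v in variants if v.chrom == model.chrom
                       and v.pos + len(v.ref) - 1 >= s and v.pos <= e]
        intron = fetch(ref, model.chrom, s, e)
        for v in intron_vars:
            if not v.is_snv:
                defects.add("splice_indel")
                continue
            intron = intron[: v.pos - s] + v.alt + intron[v.pos - s + 1 :]
        if model.strand == "-":
            intron = revcomp(intron)
        if intron[:2] != "GT":
            defects.add("splice_donor_noncanonical")
        if intron[-2:] != "AG":
            defects.add("splice_acceptor_noncanonical")

    cds = _apply_to_block(model.cds, model.strand, model.chrom, ref, variants)
    if cds is None:
        defects.add("variant_straddles_cds_edge")
        return defects
    if len(cds) % 3 != 0:
        defects.add("frameshift")
    if cds[:3] != "ATG" and cds[:3] not in _ALT_STARTS:
        defects.add("start_lost")
    protein = translate(cds)
    if "*" in protein[:-1]:
        defects.add("premature_stop")
    if not protein.endswith("*"):
        defects.add("stop_lost")
    return defects


def check_orf_restoration(
    focal: VariantSite,
    strain_variants: Sequence[VariantSite],
    model: GeneModel,
    ref,
) -> tuple[bool, str]:
    """Does the joint strain haplotype rescue a HIGH-impact focal variant?

    The focal variant is applied alone, then jointly with every other variant
    the strain carries in the transcript.  ``restored`` is True iff the focal
    variant alone disrupts the ORF (premature stop, lost start/stop codon,
    broken splice dinucleotide, or net frameshift) and the joint haplotype
    shows none of these disruptions.  Order of ``strain_variants`` is
    irrelevant and the focal variant may appear in the list.
    """
    if model.start > focal.pos or focal.pos > model.end:
        raise ValueError(
            f"focal variant {focal.chrom}:{focal.pos} outside transcript "
            f"{model.transcript_id}"
        )
    if not model.is_coding:
        raise ValueError(f"transcript {model.transcript_id} is non-coding")
    focal_defects = _high_impact_defects(model, ref, [focal])
    if not focal_defects:
        return False, "focal variant alone does not disrupt the ORF"
    joint = list({v for v in strain_variants} | {focal})
    joint_defects = _high_impact_defects(model, ref, joint)
    if joint_defects:
        return False, "joint haplotype still disrupted: " + ",".join(sorted(joint_defects))
    return True, "joint haplotype restores: " + ",".join(sorted(focal_defects))


def restoration_summary(n_dissected: int, n_restored: int) -> tuple[float, str]:
    """Percent of dissected HIGH-impact variants rescued by neighbors.

    Percentage is rounded to the nearest integer for reporting.
    """
    if n_dissected <= 0:
        raise ValueError("n_dissected must be positive")
    pct = round(100.0 * n_restored / n_dissected)
    text = (
        f"{n_restored} of {n_dissected} high-impact SNVs ({pct:.0f}%) have a "
        f"neighboring variant that restores the open reading frame"
    )
    return float(pct), text


# ---------------------------------------------------------------------------
# Ka/Ks counting
# ---------------------------------------------------------------------------

_SYN_CATS = {EffectCategory.synonymous_coding, EffectCategory.synonymous_stop}
_NONSYN_CATS = {
    EffectCategory.non_synonymous_coding,
    EffectCategory.stop_gained,
    EffectCategory.stop_lost,
    EffectCategory.start_lost,
    EffectCategory.non_synonymous_start,
}


def count_syn_nonsyn(
    gene: GeneModel, sites: Sequence[VariantSite], ref
) -> GeneSelectionStats:
    """Tally synonymous vs nonsynonymous coding SNVs in one gene.

    Nonsense and start-disrupting changes count as nonsynonymous.  Sites
    outside the CDS, non-SNVs and sites in an incomplete terminal codon are
    skipped (with a warning for the latter).
    """
    cds = coding_sequence(gene, ref)
    n_syn = n_nonsyn = 0
    for site in sites:
        if not site.is_snv or site.chrom != gene.chrom:
            continue
        cpos = _to_block_coord(gene.cds, gene.strand, site.pos)
        if cpos is None:
            continue
        _check_ref(site, ref)
        alt = site.alt if gene.strand == "+" else revcomp(site.alt)
        try:
            cat = _classify_codon_change(cds, cpos, alt)
        except _IncompleteCodon:
            warnings.warn(
                f"site {site.chrom}:{site.pos} in incomplete codon of "
                f"{gene.transcript_id}: skipped",
                stacklevel=2,
            )
            continue
        if cat in _SYN_CATS:
            n_syn += 1
        elif cat in _NONSYN_CATS:
            n_nonsyn += 1
    return GeneSelectionStats(gene.gene_id, n_nonsyn=n_nonsyn, n_syn=n_syn)


def potential_sites(gene: GeneModel, ref) -> tuple[float, float]:
    """Nei-Gojobori-style counts of potential (nonsyn, syn) sites.

    Each codon position contributes the fraction of its three possible
    substitutions that are nonsynonymous/synonymous.
    """
    cds = coding_sequence(gene, ref)
    n = s = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aa = translate(codon)
        for j in range(3):
            syn_frac = 0.0
            for b in "ACGT":
                if b == codon[j]:
                    continue
                alt_codon = codon[:j] + b + codon[j + 1 :]
                if translate(alt_codon) == aa:
                    syn_frac += 1 / 3
            s += syn_frac
            n += 1 - syn_frac
    return n, s


def site_normalized_ratio(
    gene: GeneModel, stats: GeneSelectionStats, ref
) -> float | None:
    """Ka/Ks with per-site normalization; None when undefined."""
    n_sites, s_sites = potential_sites(gene, ref)
    if stats.n_coding_snvs == 0 or n_sites == 0 or s_sites == 0:
        return None
    ka = stats.n_nonsyn / n_sites
    ks = stats.n_syn / s_sites
    return float("inf") if ks == 0 else ka / ks


def select_positive_genes(
    stats: Iterable[GeneSelectionStats], min_snvs: int
) -> list[str]:
    """Genes with >= min_snvs coding SNVs and nonsyn/syn ratio strictly > 1."""
    out = []
    for st in stats:
        r = st.ratio
        if st.n_coding_snvs >= min_snvs and r is not None and r > 1.0:
            out.append(st.gene_id)
    return out


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcript models from GFF3 (via gffutils) or BED12."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = sorted((f.start, f.end) for f in db.children(tx, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    for line in path.read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = []
        cds = []
        for size, off in zip(sizes, starts):
            s0 = chrom_start + off  # 0-based
            exons.append((s0 + 1, s0 + size))
            cs, ce = max(s0, thick_s), min(s0 + size, thick_e)
            if cs < ce:
                cds.append((cs + 1, ce))
        models.append(
            GeneModel(
                gene_id=name,
                transcript_id=name,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit GFF3 with gene -> mRNA -> exon/CDS feature hierarchy."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            chrom = txs[0].chrom
            strand = txs[0].strand
            gs = min(t.start for t in txs)
            ge = max(t.end for t in txs)
            fh.write(
                f"{chrom}\tstrainvar\tgene\t{gs}\t{ge}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in txs:
                fh.write(
                    f"{chrom}\tstrainvar\tmRNA\t{t.start}\t{t.end}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{chrom}\tstrainvar\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                phase = 0
                cds_iter = t.cds if strand == "+" else t.cds[::-1]
                for i, (s, e) in enumerate(cds_iter, 1):
                    fh.write(
                        f"{chrom}\tstrainvar\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                    )
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3
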