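"""Effect annotation, ORF restoration and syn/nonsyn counting.

The independent oracle for codon categories rebuilds the full mutant CDS,
translates both proteins with Biopython and compares them position by
position -- no shared code path with the per-codon classifier.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from strainvar import consequence
from strainvar.consequence import (
    EffectCategory,
    GeneModel,
    GeneSelectionStats,
    Impact,
    annotate_effect,
    check_orf_restoration,
    coding_sequence,
    count_syn_nonsyn,
    read_gene_models,
    restoration_summary,
    revcomp,
    select_positive_genes,
    worst_effect,
    write_gene_models_gff3,
)
from strainvar.variant_io import VariantSite

TOY_MODEL = GeneModel("g1", "g1.t1", "chr1", "+", exons=((11, 19),), cds=((11, 19),))


class TestToyCodonExamples:
    """Hand-translated single-codon cases on CDS ATG CAA TAG."""

    def test_stop_gained(self, toy_gene_ref):
        # codon 2 position 1: CAA -> TAA (stop)
        site = VariantSite("chr1", 14, "C", "T")
        ann = annotate_effect(site, [TOY_MODEL], toy_gene_ref)
        assert ann[0].category is EffectCategory.stop_gained
        assert ann[0].impact is Impact.HIGH

    def test_synonymous(self, toy_gene_ref):
        # codon 2 position 3: CAA -> CAG, both Gln
        site = VariantSite("chr1", 16, "A", "G")
        ann = annotate_effect(site, [TOY_MODEL], toy_gene_ref)
        assert ann[0].category is EffectCategory.synonymous_coding
        assert ann[0].impact is Impact.LOW

    def test_nonsynonymous(self, toy_gene_ref):
        # codon 2 position 2: CAA -> CGA (Gln -> Arg)
        site = VariantSite("chr1", 15, "A", "G")
        ann = annotate_effect(site, [TOY_MODEL], toy_gene_ref)
        assert ann[0].category is EffectCategory.non_synonymous_coding
        assert ann[0].impact is Impact.MODERATE

    def test_start_lost_and_alt_start(self, toy_gene_ref):
        lost = annotate_effect(VariantSite("chr1", 12, "T", "A"), [TOY_MODEL],
                               toy_gene_ref)
        assert lost[0].category is EffectCategory.start_lost
        # ATG -> GTG is an alternative initiation codon
        alt = annotate_effect(VariantSite("chr1", 11, "A", "G"), [TOY_MODEL],
                              toy_gene_ref)
        assert alt[0].category is EffectCategory.non_synonymous_start
        assert alt[0].impact is Impact.LOW

    def test_stop_lost_and_synonymous_stop(self, toy_gene_ref):
        lost = annotate_effect(VariantSite("chr1", 18, "A", "C"), [TOY_MODEL],
                               toy_gene_ref)
        assert lost[0].category is EffectCategory.stop_lost
        syn = annotate_effect(VariantSite("chr1", 19, "G", "A"), [TOY_MODEL],
                              toy_gene_ref)  # TAG -> TAA, still stop
        assert syn[0].category is EffectCategory.synonymous_stop

    def test_intergenic_default(self, toy_gene_ref):
        # > 5 kb from any transcript on a long contig
        ref = {"chr1": toy_gene_ref["chr1"] + "A" * 10_000}
        site = VariantSite("chr1", 9_000, "A", "C")
        ann = annotate_effect(site, [TOY_MODEL], ref)
        assert len(ann) == 1
        assert ann[0].category is EffectCategory.intergenic
        assert ann[0].impact is Impact.MODIFIER
        assert ann[0].gene_id is None

    def test_reference_mismatch_raises(self, toy_gene_ref):
        with pytest.raises(ValueError, match="reference mismatch"):
            annotate_effect(VariantSite("chr1", 14, "G", "T"), [TOY_MODEL],
                            toy_gene_ref)


@pytest.fixture(scope="module")
def spliced_ref():
    # CDS ATGCAATGC + intron GT(...)AG + GCTCTATAG
    seq = "A" * 10 + "ATGCAATGC" + "GT" + "C" * 16 + "AG" + "GCTCTATAG"
    return {"chr1": seq + "A" * 6_000}


class TestNonCodingRegions:
    # gene with two exons and one intron: exons 11-19 / 40-48, intron 20-39
    SPLICED = GeneModel(
        "g2", "g2.t1", "chr1", "+", exons=((11, 19), (40, 48)),
        cds=((11, 19), (40, 48)),
    )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (20, EffectCategory.splice_site_donor),
            (21, EffectCategory.splice_site_donor),
            (38, EffectCategory.splice_site_acceptor),
            (39, EffectCategory.splice_site_acceptor),
            (30, EffectCategory.intron),
        ],
    )
    def test_splice_and_intron(self, spliced_ref, pos, expected):
        base = spliced_ref["chr1"][pos - 1]
        alt = "A" if base != "A" else "C"
        ann = annotate_effect(VariantSite("chr1", pos, base, alt),
                              [self.SPLICED], spliced_ref)
        assert ann[0].category is expected

    def test_upstream_downstream_strand_aware(self, spliced_ref):
        site = VariantSite("chr1", 5, "A", "C")
        assert annotate_effect(site, [self.SPLICED], spliced_ref)[0].category is \
            EffectCategory.upstream
        minus = GeneModel("g2", "g2.t2", "chr1", "-",
                          exons=self.SPLICED.exons, cds=self.SPLICED.cds)
        assert annotate_effect(site, [minus], spliced_ref)[0].category is \
            EffectCategory.downstream


class TestBruteForceOracle:
    """Per-codon classifier agrees with full-CDS rebuild-and-translate."""

    def oracle_category(self, model, site, ref):
        cds = coding_sequence(model, ref)
        cpos = consequence._to_block_coord(model.cds, model.strand, site.pos)
        alt = site.alt if model.strand == "+" else revcomp(site.alt)
        mutant = cds[:cpos] + alt + cds[cpos + 1 :]
        p_ref = str(Seq(cds).translate())
        p_alt = str(Seq(mutant).translate())
        codon_i = cpos // 3
        if codon_i == 0:
            return (
                EffectCategory.non_synonymous_start
                if mutant[:3] in ("CTG", "GTG", "TTG")
                else EffectCategory.start_lost
            )
        if p_ref[codon_i] == "*":
            return (
                EffectCategory.synonymous_stop
                if p_alt[codon_i] == "*"
                else EffectCategory.stop_lost
            )
        if p_alt[codon_i] == "*":
            return EffectCategory.stop_gained
        if p_ref == p_alt:
            return EffectCategory.synonymous_coding
        return EffectCategory.non_synonymous_coding

    def test_all_coding_positions_all_alts(self, gene_bundle):
        models, _, ref = gene_bundle
        from strainvar.synthetic import _coding_to_genomic

        checked = 0
        for model in models[:8]:
            for cpos in range(model.coding_length):
                gpos = _coding_to_genomic(model, cpos)
                ref_base = ref[model.chrom][gpos - 1]
                for alt_genomic in "ACGT":
                    if alt_genomic == ref_base:
                        continue
                    site = VariantSite(model.chrom, gpos, ref_base, alt_genomic)
                    got = annotate_effect(site, [model], ref)[0].category
                    want = self.oracle_category(model, site, ref)
                    assert got is want, (model.transcript_id, cpos, site)
                    checked += 1
        assert checked > 1000

    def test_strand_symmetry(self, toy_gene_ref):
        """A minus-strand gene over the reverse-complemented sequence yields
        the same category for the corresponding variant."""
        seq = toy_gene_ref["chr1"]
        n = len(seq)
        flipped = {"chr1": revcomp(seq)}
        minus_model = GeneModel(
            "g1", "g1.t1", "chr1", "-",
            exons=((n - 19 + 1, n - 11 + 1),), cds=((n - 19 + 1, n - 11 + 1),),
        )
        for pos, ref_b, alt_b in [(14, "C", "T"), (16, "A", "G"), (15, "A", "G")]:
            plus_cat = annotate_effect(
                VariantSite("chr1", pos, ref_b, alt_b), [TOY_MODEL], toy_gene_ref
            )[0].category
            mpos = n - pos + 1
            minus_cat = annotate_effect(
                VariantSite("chr1", mpos, revcomp(ref_b), revcomp(alt_b)),
                [minus_model],
                flipped,
            )[0].category
            assert plus_cat is minus_cat


def test_worst_effect_is_max_impact(toy_gene_ref):
    site = VariantSite("chr1", 14, "C", "T")
    other = GeneModel("g9", "g9.t1", "chr1", "+", exons=((5, 30),))  # non-coding
    anns = annotate_effect(site, [other, TOY_MODEL], toy_gene_ref)
    assert len(anns) == 2
    assert worst_effect(anns).impact is Impact.HIGH
    assert worst_effect(anns).category is EffectCategory.stop_gained


class TestOrfRestoration:
    def test_same_codon_second_hit_restores(self, toy_gene_ref):
        focal = VariantSite("chr1", 14, "C", "T")  # CAA -> TAA
        partner = VariantSite("chr1", 15, "A", "C")  # joint TCA = Ser
        restored, reason = check_orf_restoration(
            focal, [partner], TOY_MODEL, toy_gene_ref
        )
        assert restored and "premature_stop" in reason

    def test_no_neighbors_not_restored(self, toy_gene_ref):
        focal = VariantSite("chr1", 14, "C", "T")
        restored, _ = check_orf_restoration(focal, [], TOY_MODEL, toy_gene_ref)
        assert not restored

    def test_order_independent_and_idempotent(self, gene_bundle):
        models, planted, ref = gene_bundle
        pairs = [p for p in planted if p.partner is not None]
        assert pairs
        for p in pairs:
            model = next(m for m in models if m.transcript_id == p.transcript_id)
            a = check_orf_restoration(p.focal, [p.partner], model, ref)
            b = check_orf_restoration(p.focal, [p.partner, p.focal], model, ref)
            c = check_orf_restoration(p.focal, [p.focal, p.partner], model, ref)
            assert a == b == c

    def test_planted_rescue_fraction_recovered(self, gene_bundle):
        models, planted, ref = gene_bundle
        by_tx = {m.transcript_id: m for m in models}
        flags = []
        for p in planted:
            neighbors = [p.partner] if p.partner else []
            restored, _ = check_orf_restoration(
                p.focal, neighbors, by_tx[p.transcript_id], ref
            )
            flags.append(restored)
            assert restored == p.rescued
        assert sum(flags) == sum(p.rescued for p in planted)

    def test_focal_outside_transcript_raises(self, toy_gene_ref):
        ref = {"chr1": toy_gene_ref["chr1"] + "A" * 100}
        focal = VariantSite("chr1", 100, "A", "C")
        with pytest.raises(ValueError, match="outside transcript"):
            check_orf_restoration(focal, [], TOY_MODEL, ref)

    def test_frameshift_pair_restores_frame(self, toy_gene_ref):
        """A 1 nt deletion plus a 2 nt deletion net a full codon: in-frame."""
        model = GeneModel("g1", "g1.t1", "chr1", "+",
                          exons=((11, 25),), cds=((11, 25),))
        # CDS = ATG CAA TAG CCC CCC -> use a clean CDS without internal stop
        seq = "A" * 10 + "ATGCAATGGCCCTAG" + "C" * 20
        ref = {"chr1": seq}
        fs = VariantSite("chr1", 14, "CA", "C")  # -1 frameshift
        rescue = VariantSite("chr1", 18, "GGC", "G")  # -2, net -3
        restored_alone, _ = check_orf_restoration(fs, [], model, ref)
        assert not restored_alone
        restored, _ = check_orf_restoration(fs, [rescue], model, ref)
        assert restored


def test_restoration_summary_bookkeeping():
    pct, text = restoration_summary(601, 60)
    assert pct == 10.0
    assert "10%" in text


class TestSynNonsyn:
    def test_no_coding_snvs(self, toy_gene_ref):
        st = count_syn_nonsyn(TOY_MODEL, [], toy_gene_ref)
        assert st.n_coding_snvs == 0 and st.ratio is None

    def test_planted_four_nonsyn_two_syn(self):
        # CDS of 8 codons with known syn/nonsyn substitutions
        cds = "ATG" + "CAA" * 6 + "TAG"
        seq = "A" * 10 + cds + "C" * 10
        model = GeneModel("g", "g.t1", "chr1", "+",
                          exons=((11, 10 + len(cds)),), cds=((11, 10 + len(cds)),))
        ref = {"chr1": seq}
        # CAA codons start at 14, 17, 20, 23, 26, 29
        nonsyn = [VariantSite("chr1", p, "A", "G") for p in (15, 18, 21, 24)]
        syn = [VariantSite("chr1", p + 2, "A", "G") for p in (26, 29)]
        st = count_syn_nonsyn(model, nonsyn + syn, ref)
        assert (st.n_nonsyn, st.n_syn) == (4, 2)
        assert st.ratio == 2.0

    def test_all_synonymous_ratio_zero(self, toy_gene_ref):
        syn = [VariantSite("chr1", 16, "A", "G")]
        st = count_syn_nonsyn(TOY_MODEL, syn, toy_gene_ref)
        assert st.ratio == 0.0

    def test_zero_syn_encoded_as_inf(self):
        st = GeneSelectionStats("g", n_nonsyn=3, n_syn=0)
        assert st.ratio == float("inf")


class TestSelectPositiveGenes:
    def test_threshold_semantics(self):
        stats = [
            GeneSelectionStats("a", 4, 2),  # 6 SNVs, ratio 2.0 -> selected
            GeneSelectionStats("b", 3, 3),  # 6 SNVs, ratio 1.0 -> excluded
            GeneSelectionStats("c", 4, 1),  # 5 SNVs -> excluded
        ]
        assert select_positive_genes(stats, min_snvs=6) == ["a"]

    def test_empty(self):
        assert select_positive_genes([], 6) == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(13)
        stats = [
            GeneSelectionStats(f"g{i}", int(rng.integers(0, 10)),
                               int(rng.integers(0, 10)))
            for i in range(100)
        ]
        got = select_positive_genes(stats, 6)
        want = [
            s.gene_id
            for s in stats
            if s.n_nonsyn + s.n_syn >= 6
            and (s.n_syn == 0 and s.n_nonsyn > 0 or s.n_syn > 0 and
                 s.n_nonsyn / s.n_syn > 1.0)
        ]
        assert got == want


def test_gff3_round_trip(tmp_path, gene_bundle):
    models, _, _ = gene_bundle
    p = tmp_path / "models.gff3"
    write_gene_models_gff3(models, p)
    back = read_gene_models(p)
    by_tx = {m.transcript_id: m for m in back}
    for m in models:
        b = by_tx[m.transcript_id]
        assert (b.exons, b.cds, b.strand, b.chrom) == (
            m.exons, m.cds, m.strand, m.chrom
        )


def test_site_normalized_mode_available(toy_gene_ref):
    st = count_syn_nonsyn(
        TOY_MODEL, [VariantSite("chr1", 15, "A", "G")], toy_gene_ref
    )
    r = consequence.site_normalized_ratio(TOY_MODEL, st, toy_gene_ref)
    assert r == float("inf")  # one nonsyn, zero syn observed
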