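import pytest
from Bio.Seq import Seq

from evopool.annotate import (
    GeneModel,
    annotate_call,
    classify_region,
    codon_effect,
    load_genbank,
    load_gff3,
)
from evopool.caller import VariantCall
from evopool.errors import AnnotationError, InvalidArgument
from evopool.sim import ReferenceGenome
from evopool._seq import revcomp

#            codon:   1    2    3    4    5    6    7    8    9    10
CDS = "".join(["ATG", "GGA", "TAT", "CTG", "TGG", "GCA", "AAA", "CCC", "GGG", "TAA"])
PAD = "ACGTACGTAC" * 10  # 100 bp of neutral padding


def _reference():
    # CDS occupies 101..130 on the forward strand
    return ReferenceGenome([("chrF", PAD + CDS + PAD)])


def _reference_rev():
    # reverse-complement CDS occupies 101..130; gene is on the minus strand
    return ReferenceGenome([("chrR", PAD + revcomp(CDS) + PAD)])


def _gene(strand="+", contig="chrF"):
    return GeneModel("tg_0001", contig, strand, ((101, 130),), "fixture protein")


def _snp_call(pos, ref, alt, contig="chrF", kind="snp"):
    return VariantCall(contig, pos, ref, alt, kind, 0.5, 100, 200, 50.0, 0.5)


class TestGeneModel:
    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(InvalidArgument):
            GeneModel("g", "c", "+", ((1, 10),))

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InvalidArgument):
            GeneModel("g", "c", "+", ((1, 6), (4, 9)))


class TestClassifyRegion:
    def test_inside_cds_is_coding(self):
        out = classify_region(_snp_call(115, "T", "C"), [_gene()])
        assert out.region == "coding" and out.gene_ids == ("tg_0001",)

    def test_upstream_within_window_is_promoter_proximal(self):
        out = classify_region(_snp_call(51, "A", "G"), [_gene()], promoter_window=150)
        assert out.region == "promoter_proximal"
        assert out.gene_ids == ("tg_0001",)

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self):
        out = classify_region(
            _snp_call(180, "A", "G", contig="chrR"), [_gene("-", "chrR")], promoter_window=150
        )
        assert out.region == "promoter_proximal"

    def test_outside_window_is_intergenic_with_flanks(self):
        g1 = _gene()
        g2 = GeneModel("tg_0002", "chrF", "+", ((191, 220),))
        out = classify_region(_snp_call(160, "A", "G"), [g1, g2], promoter_window=20)
        assert out.region == "intergenic"
        assert set(out.gene_ids) == {"tg_0001", "tg_0002"}

    def test_equidistant_puts_upstream_gene_first(self):
        g1 = GeneModel("left", "chrF", "-", ((2, 31),))      # call is upstream of 'left'
        g2 = GeneModel("right", "chrF", "+", ((101, 130),))  # promoter window excluded
        out = classify_region(_snp_call(66, "A", "G"), [g1, g2], promoter_window=10)
        assert out.gene_ids[0] == "left"  # tie at 35 bp; upstream-facing gene first


class TestCodonEffect:
    def test_gga_to_gaa_is_gly_to_glu(self):
        # codon 2 (GGA) at 104..106; G->A at the middle base
        call = _snp_call(105, "G", "A")
        out = codon_effect(call, _gene(), _reference())
        assert (out.codon_ref, out.codon_alt) == ("GGA", "GAA")
        assert (out.aa_ref, out.aa_pos, out.aa_alt) == ("G", 2, "E")
        assert out.effect == "nonsynonymous"
        assert out.notation == "G2E"

    def test_tat_to_tct_is_tyr_to_ser(self):
        # codon 3 (TAT) at 107..109; A->C at the middle base
        call = _snp_call(108, "A", "C")
        out = codon_effect(call, _gene(), _reference())
        assert (out.codon_ref, out.codon_alt) == ("TAT", "TCT")
        assert (out.aa_ref, out.aa_alt) == ("Y", "S")
        assert out.effect == "nonsynonymous"

    def test_ctg_to_ttg_is_synonymous(self):
        call = _snp_call(110, "C", "T")
        out = codon_effect(call, _gene(), _reference())
        assert (out.codon_ref, out.codon_alt) == ("CTG", "TTG")
        assert out.effect == "synonymous"

    def test_stop_gain_is_nonsense(self):
        # codon 5 (TGG) at 113..115; G->A at middle base gives TAG
        call = _snp_call(114, "G", "A")
        out = codon_effect(call, _gene(), _reference())
        assert out.effect == "nonsense" and out.aa_alt == "*"

    def test_frameshift_and_in_frame_indels(self):
        ref = _reference()
        fs = VariantCall("chrF", 110, "CT", "C", "deletion", 1.0, 10, 10, 0.0, 1.0)
        assert codon_effect(fs, _gene(), ref).effect == "frameshift"
        inframe = VariantCall("chrF", 110, "CTGT", "C", "deletion", 1.0, 10, 10, 0.0, 1.0)
        assert codon_effect(inframe, _gene(), ref).effect == "in_frame_indel"

    def test_inconsistent_reference_raises(self):
        call = _snp_call(105, "T", "A")  # claims ref T where reference has G
        with pytest.raises(AnnotationError):
            codon_effect(call, _gene(), _reference())

    def test_reverse_strand_metamorphic(self):
        """A minus-strand gene yields the identical consequence as its
        forward-strand mirror annotated on the reverse complement."""
        fwd_ref, rev_ref = _reference(), _reference_rev()
        fwd_gene, rev_gene = _gene(), _gene("-", "chrR")
        for fwd_pos, ref_b, alt_b in [(105, "G", "A"), (108, "A", "C"), (110, "C", "T")]:
            fwd_out = codon_effect(_snp_call(fwd_pos, ref_b, alt_b), fwd_gene, fwd_ref)
            # mirror position: CDS offset o maps to 130 - o on the reverse copy
            off = fwd_pos - 101
            rev_pos = 130 - off
            rev_out = codon_effect(
                _snp_call(rev_pos, revcomp(ref_b), revcomp(alt_b), contig="chrR"),
                rev_gene,
                rev_ref,
            )
            assert (rev_out.codon_ref, rev_out.codon_alt) == (fwd_out.codon_ref, fwd_out.codon_alt)
            assert (rev_out.aa_ref, rev_out.aa_pos, rev_out.aa_alt) == (
                fwd_out.aa_ref, fwd_out.aa_pos, fwd_out.aa_alt,
            )
            assert rev_out.effect == fwd_out.effect

    @pytest.mark.parametrize("offset", range(0, 30, 4))
    def test_against_whole_cds_translation_oracle(self, offset):
        """Brute force: mutate the CDS string, translate both, diff the proteins."""
        ref = _reference()
        gene = _gene()
        pos = 101 + offset
        ref_b = CDS[offset]
        alt_b = {"A": "G", "C": "T", "G": "C", "T": "A"}[ref_b]
        out = codon_effect(_snp_call(pos, ref_b, alt_b), gene, ref)
        mutated = CDS[:offset] + alt_b + CDS[offset + 1 :]
        prot_ref = str(Seq(CDS).translate(table=11))
        prot_alt = str(Seq(mutated).translate(table=11))
        diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
        if not diffs:
            assert out.effect == "synonymous"
        else:
            (i,) = diffs
            assert out.aa_pos == i + 1
            assert out.aa_ref == prot_ref[i]
            assert out.aa_alt == prot_alt[i]


class TestAnnotateCall:
    def test_dispatch_coding_vs_intergenic(self):
        ref = _reference()
        coding = annotate_call(_snp_call(105, "G", "A"), [_gene()], ref)
        assert coding.effect == "nonsynonymous"
        intergenic = annotate_call(_snp_call(300, "A", "G"), [_gene()], ref, promoter_window=10)
        assert intergenic.region == "intergenic"


class TestGeneModelReaders:
    def test_gff3_roundtrip(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrF\tsrc\tgene\t101\t130\t.\t+\t.\tID=gene1;locus_tag=tg_0001\n"
            "chrF\tsrc\tCDS\t101\t130\t0\t+\t0\tID=cds1;Parent=gene1;locus_tag=tg_0001;product=fixture protein\n"
        )
        (g,) = load_gff3(gff)
        assert g.gene_id == "tg_0001"
        assert g.cds_intervals == ((101, 130),)
        assert g.strand == "+"
        assert g.product == "fixture protein"

    def test_genbank_roundtrip(self, tmp_path):
        from Bio.Seq import Seq as BSeq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        rec = SeqRecord(BSeq(PAD + CDS + PAD), id="chrF", annotations={"molecule_type": "DNA"})
        rec.features.append(
            SeqFeature(
                FeatureLocation(100, 130, strand=1),
                type="CDS",
                qualifiers={"locus_tag": ["tg_0001"], "product": ["fixture protein"]},
            )
        )
        path = tmp_path / "g.gbk"
        SeqIO.write([rec], str(path), "genbank")
        (g,) = load_genbank(path)
        assert g.gene_id == "tg_0001"
        assert g.cds_intervals == ((101, 130),)
        assert g.cds_sequence(_reference()) == CDS
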