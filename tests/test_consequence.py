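"""Consequence engine: CDS building, classification, labels, oracles."""

import numpy as np
import pytest

from neoforge.consequence import (
    ProteinConsequence,
    TranscriptModel,
    annotate,
    build_cds,
    hgvs_like_label,
    read_gtf,
    revcomp,
    write_gtf,
)
from neoforge.errors import CoordinateError, LabelError, NormalizationError
from neoforge.vcf_ops import VariantRecord
from oracles import mirror_construction, oracle_consequence


class TestBuildCds:
    def test_plus_strand_single_segment(self):
        genome = {"c": "GGGGGGGGGG" + "ATGCTGGAA" + "G"}
        t = TranscriptModel("t1", "g1", "c", "+", [(11, 19)])
        seq, gmap = build_cds(t, genome)
        assert seq == "ATGCTGGAA"
        assert gmap[11] == 0 and gmap[19] == 8

    def test_minus_strand_reverse_complement(self):
        genome = {"c": "G" + "TTCCAGCAT" + "GGGGGGGGGG"}
        t = TranscriptModel("t1", "g1", "c", "-", [(2, 10)])
        seq, gmap = build_cds(t, genome)
        assert seq == "ATGCTGGAA"
        assert gmap[10] == 0 and gmap[2] == 8  # 5' end is the genomic right

    def test_two_exon_concatenation(self):
        genome = {"c": "ATG" + "GTTTAG" + "CTGGAA" + "T"}
        t = TranscriptModel("t1", "g1", "c", "+", [(1, 3), (10, 15)])
        seq, _ = build_cds(t, genome)
        assert seq == "ATGCTGGAA"
        assert len(seq) == t.cds_length

    def test_out_of_bounds_segment(self):
        t = TranscriptModel("t1", "g1", "c", "+", [(1, 50)])
        with pytest.raises(CoordinateError):
            build_cds(t, {"c": "ATGCTG"})


class TestAnnotate:
    def test_missense_ctg_to_cgg(self, toy_gene):
        genome, t = toy_gene
        # codon 2 CTG -> CGG (Leu -> Arg); CDS offset 4 is genomic 9
        (c,) = annotate(VariantRecord("chrT", 9, "T", ["G"]), [t], genome)
        assert (c.classification, c.protein_position, c.ref_aa, c.alt_aa) == (
            "missense", 2, "L", "R",
        )
        assert c.label == "L2R"

    def test_synonymous_ctg_to_cta(self, toy_gene):
        genome, t = toy_gene
        (c,) = annotate(VariantRecord("chrT", 10, "G", ["A"]), [t], genome)
        assert (c.classification, c.protein_position) == ("synonymous", 2)
        assert c.ref_aa == c.alt_aa == "L"

    def test_stop_gained_tgg_to_tga(self):
        genome = {"c": "ATGTGGGAATAA"}
        t = TranscriptModel("t1", "g1", "c", "+", [(1, 12)])
        (c,) = annotate(VariantRecord("c", 6, "G", ["A"]), [t], genome)
        assert (c.classification, c.protein_position, c.alt_aa) == ("stop_gained", 2, "*")

    def test_frameshift_deletion(self, toy_gene):
        genome, t = toy_gene
        (c,) = annotate(VariantRecord("chrT", 8, "CT", ["C"]), [t], genome)
        assert c.classification == "frameshift"

    def test_noncoding_outside_all_cds(self, toy_gene):
        genome, t = toy_gene
        assert annotate(VariantRecord("chrT", 1, "G", ["A"]), [t], genome) == []

    def test_splice_region_at_internal_junction(self):
        genome = {"c": "ATG" + "GTTTAG" + "CTGGAATAA" + "T"}
        t = TranscriptModel("t1", "g1", "c", "+", [(1, 3), (10, 18)])
        (c,) = annotate(VariantRecord("c", 4, "G", ["A"]), [t], genome)
        assert c.classification == "splice_region"

    def test_deep_intron_is_non_coding(self):
        genome = {"c": "ATG" + "GT" + "T" * 20 + "AG" + "CTGGAATAA" + "T"}
        t = TranscriptModel("t1", "g1", "c", "+", [(1, 3), (28, 36)])
        (c,) = annotate(VariantRecord("c", 15, "T", ["A"]), [t], genome)
        assert c.classification == "non_coding"

    def test_multiallelic_rejected(self, toy_gene):
        genome, t = toy_gene
        with pytest.raises(NormalizationError):
            annotate(VariantRecord("chrT", 10, "T", ["G", "A"]), [t], genome)

    def test_consequence_count_equals_overlapping_transcripts(self, study):
        bundle = study["bundle"]
        for rec in study["somatic"][:10]:
            cons = annotate(rec, bundle.transcripts, bundle.chromosomes)
            overlapping = [
                t for t in bundle.transcripts
                if t.chrom == rec.chrom
                and rec.end >= t.span[0] - 2 and rec.pos <= t.span[1] + 2
            ]
            assert len(cons) == len(overlapping)


class TestLabels:
    @pytest.mark.parametrize(
        "cls, pos, ra, aa, expect",
        [
            ("missense", 4492, "L", "R", "L4492R"),
            ("stop_gained", 10, "W", "*", "W10*"),
            ("missense", 1, "M", "T", "M1T"),
        ],
    )
    def test_substitution_labels(self, cls, pos, ra, aa, expect):
        c = ProteinConsequence("t1", cls, protein_position=pos, ref_aa=ra, alt_aa=aa)
        assert hgvs_like_label(c) == expect

    def test_inapplicable_class_raises(self):
        c = ProteinConsequence("t1", "frameshift", protein_position=5, ref_aa="K")
        with pytest.raises(LabelError):
            hgvs_like_label(c)


def _random_cds_variants(bundle, rng, n):
    """Random SNVs and small indels confined to single CDS segments."""
    out = []
    while len(out) < n:
        t = bundle.transcripts[rng.integers(len(bundle.transcripts))]
        s0, e0 = t.cds_segments[rng.integers(len(t.cds_segments))]
        if e0 - s0 < 8:
            continue
        pos = int(rng.integers(s0 + 2, e0 - 3))
        seq = bundle.chromosomes[t.chrom]
        kind = rng.integers(3)
        if kind == 0:  # SNV
            ref = seq[pos - 1]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref:
                continue
            alts = [alt]
        elif kind == 1:  # deletion of 1-2 bases, anchored
            dlen = int(rng.integers(1, 3))
            if pos + dlen > e0:
                continue
            ref = seq[pos - 1 : pos + dlen]
            alts = [seq[pos - 1]]
        else:  # insertion of 1-2 bases after the anchor
            ref = seq[pos - 1]
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 3)))
            alts = [ref + ins]
        out.append((VariantRecord(t.chrom, pos, ref, alts), t))
    return out


class TestOracleEquivalence:
    def test_engine_matches_full_retranslation(self, study):
        """>=500 random variants: CDS-splice route vs genome-mutation route."""
        bundle = study["bundle"]
        rng = np.random.default_rng(123)
        for rec, t in _random_cds_variants(bundle, rng, 520):
            cons = [
                c for c in annotate(rec, bundle.transcripts, bundle.chromosomes)
                if c.transcript_id == t.transcript_id
            ][0]
            cls, pos, ra, aa = oracle_consequence(rec, t, bundle.chromosomes)
            assert cons.classification == cls, (rec, cons, cls)
            if cls in ("synonymous", "missense", "stop_gained", "stop_lost"):
                assert (cons.protein_position, cons.ref_aa, cons.alt_aa) == (pos, ra, aa)

    def test_strand_symmetry(self, study):
        """Mirrored construction yields identical protein consequences."""
        bundle = study["bundle"]
        rng = np.random.default_rng(321)
        for rec, t in _random_cds_variants(bundle, rng, 60):
            chrom_seq = bundle.chromosomes[t.chrom]
            m_seq, m_t, m_var = mirror_construction(chrom_seq, t, rec)
            orig = [
                c for c in annotate(rec, [t], {t.chrom: chrom_seq})
            ][0]
            mirrored = [c for c in annotate(m_var, [m_t], {t.chrom: m_seq})][0]
            assert orig.classification == mirrored.classification
            assert orig.protein_position == mirrored.protein_position
            assert (orig.ref_aa, orig.alt_aa) == (mirrored.ref_aa, mirrored.alt_aa)


class TestGtfRoundTrip:
    def test_models_survive_write_read(self, tmp_path, study):
        path = tmp_path / "genes.gtf"
        transcripts = study["bundle"].transcripts
        write_gtf(path, transcripts)
        back = read_gtf(path)
        assert len(back) == len(transcripts)
        by_id = {t.transcript_id: t for t in back}
        for t in transcripts:
            m = by_id[t.transcript_id]
            assert (m.chrom, m.strand, m.cds_segments) == (
                t.chrom, t.strand, t.cds_segments,
            )
            assert m.gene_id == t.gene_id
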