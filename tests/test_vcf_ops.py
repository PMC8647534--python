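"""Normalization (splitting, left-alignment) and site-filter behavior."""

import random
import subprocess

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoforge.errors import OrderingError, ReferenceMismatchError
from neoforge.vcf_ops import (
    VariantRecord,
    apply_site_filters,
    left_align_and_trim,
    normalize_records,
    read_vcf,
    split_multiallelic,
    write_vcf,
)
from oracles import brute_force_cluster_flags, brute_force_normalize


def _apply(seq: str, pos: int, ref: str, alt: str) -> str:
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


class TestSplitMultiallelic:
    def test_two_alts_split_in_order(self):
        rec = VariantRecord("chr1", 100, "A", ["T", "G"], info={"FS": 1.0})
        out = split_multiallelic(rec)
        assert [(r.pos, r.ref, r.alt) for r in out] == [(100, "A", "T"), (100, "A", "G")]
        assert all(r.info == {"FS": 1.0} for r in out)

    def test_biallelic_passes_through(self):
        rec = VariantRecord("chr1", 100, "A", ["T"])
        (out,) = split_multiallelic(rec)
        assert (out.chrom, out.pos, out.ref, out.alt) == ("chr1", 100, "A", "T")

    def test_mixed_indel_alleles_normalize_independently(self):
        # AT -> [A, ATT]: a deletion and an insertion sharing one record
        seq = "GGATGG"
        rec = VariantRecord("chr1", 3, "AT", ["A", "ATT"])
        out = [left_align_and_trim(r, seq) for r in split_multiallelic(rec)]
        for r, alt in zip(out, rec.alts):
            expect = brute_force_normalize(3, "AT", alt, seq)
            assert (r.pos, r.ref, r.alt) == expect
        # haplotypes preserved through split + normalization
        assert {_apply(seq, r.pos, r.ref, r.alt) for r in out} == {
            _apply(seq, 3, "AT", a) for a in rec.alts
        }


class TestLeftAlign:
    def test_repeat_deletion_shifts_to_leftmost_copy(self):
        seq = "GCACACACAG"
        # deletion of one CA unit written at the rightmost copy
        rec = VariantRecord("chr1", 7, "ACA", ["A"])
        out = left_align_and_trim(rec, seq)
        expect = brute_force_normalize(7, "ACA", "A", seq)
        assert (out.pos, out.ref, out.alt) == expect
        assert out.pos < rec.pos
        assert _apply(seq, out.pos, out.ref, out.alt) == _apply(seq, 7, "ACA", "A")

    def test_snv_unchanged(self):
        seq = "GCACACACAG"
        rec = VariantRecord("chr1", 4, "C", ["T"])
        out = left_align_and_trim(rec, seq)
        assert (out.pos, out.ref, out.alt) == (4, "C", "T")

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            left_align_and_trim(VariantRecord("chr1", 1, "T", ["G"]), "AAAA")

    def test_contig_start_keeps_anchor(self):
        # deletion in a homopolymer running to the contig start
        seq = "AAAATG"
        out = left_align_and_trim(VariantRecord("chr1", 3, "AA", ["A"]), seq)
        assert (out.pos, out.ref, out.alt) == brute_force_normalize(3, "AA", "A", seq)
        assert out.pos == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_and_idempotent(self, data):
        seq = "".join(data.draw(st.lists(st.sampled_from("ACGT"), min_size=20, max_size=50)))
        pos = data.draw(st.integers(2, len(seq) - 4))
        if data.draw(st.booleans()):  # deletion
            dlen = data.draw(st.integers(1, 3))
            ref = seq[pos - 1 : pos + dlen]
            alt = seq[pos - 1]
        else:  # insertion
            ref = seq[pos - 1]
            alt = ref + "".join(data.draw(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=3)))
        if ref == alt:
            return
        rec = VariantRecord("chr1", pos, ref, [alt])
        out = left_align_and_trim(rec, seq)
        assert (out.pos, out.ref, out.alt) == brute_force_normalize(pos, ref, alt, seq)
        again = left_align_and_trim(out, seq)
        assert (again.pos, again.ref, again.alt) == (out.pos, out.ref, out.alt)


class TestAgainstBcftools:
    def test_left_alignment_matches_bcftools_norm(self, tmp_path):
        """bcftools norm as an independent oracle on random indels."""
        rng = random.Random(11)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        genome = {"chr1": seq}
        records = []
        for _ in range(30):
            pos = rng.randrange(5, 390)
            if rng.random() < 0.5:
                dlen = rng.randint(1, 3)
                ref, alt = seq[pos - 1 : pos + dlen], seq[pos - 1]
            else:
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            if ref != alt:
                records.append(VariantRecord("chr1", pos, ref, [alt]))
        records.sort(key=lambda r: r.pos)

        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr1\n" + seq + "\n")
        vcf_in = tmp_path / "in.vcf"
        write_vcf(vcf_in, records, {"chr1": len(seq)})
        proc = subprocess.run(
            ["bcftools", "norm", "-f", str(fasta), str(vcf_in)],
            capture_output=True, text=True, check=True,
        )
        norm_out = tmp_path / "norm.vcf"
        norm_out.write_text(proc.stdout)
        theirs = {(r.pos, r.ref, r.alt) for r in read_vcf(norm_out)}
        ours = {(r.pos, r.ref, r.alt) for r in normalize_records(records, genome)}
        assert ours == theirs


class TestSiteFilters:
    def _rec(self, pos, **info):
        return VariantRecord("chr1", pos, "A", ["G"], info=info)

    @pytest.mark.parametrize(
        "fs, flagged", [(35.0, True), (30.1, True), (30.0, False), (29.9, False)]
    )
    def test_fs_strict_boundary(self, fs, flagged):
        (out,) = apply_site_filters([self._rec(100, FS=fs, QD=20.0)])
        assert ("FS" in out.filter_flags) is flagged

    @pytest.mark.parametrize(
        "qd, flagged", [(1.9, True), (1.99, True), (2.0, False), (2.1, False)]
    )
    def test_qd_strict_boundary(self, qd, flagged):
        (out,) = apply_site_filters([self._rec(100, FS=1.0, QD=qd)])
        assert ("QD" in out.filter_flags) is flagged

    def test_cluster_span_34_flags_all_three(self):
        recs = [self._rec(p, FS=1.0, QD=20.0) for p in (100, 117, 134)]
        out = apply_site_filters(recs)
        assert all("SnpCluster" in r.filter_flags for r in out)

    def test_sparse_snvs_not_flagged(self):
        recs = [self._rec(p, FS=1.0, QD=20.0) for p in (100, 150, 200)]
        out = apply_site_filters(recs)
        assert all(r.is_pass for r in out)

    def test_indels_ignored_for_clustering(self):
        recs = [
            VariantRecord("chr1", 100, "AT", ["A"], info={"FS": 1.0, "QD": 20.0}),
            self._rec(110, FS=1.0, QD=20.0),
            self._rec(120, FS=1.0, QD=20.0),
        ]
        out = apply_site_filters(recs)
        assert all(r.is_pass for r in out)

    def test_missing_annotation_passes_that_rule(self):
        (out,) = apply_site_filters([self._rec(100)])
        assert out.is_pass

    def test_unsorted_input_raises(self):
        recs = [self._rec(200, FS=1.0, QD=20.0), self._rec(100, FS=1.0, QD=20.0)]
        with pytest.raises(OrderingError):
            apply_site_filters(recs)

    def test_input_records_unmodified(self):
        recs = [self._rec(p, FS=50.0, QD=20.0) for p in (100, 110, 120)]
        apply_site_filters(recs)
        assert all(r.is_pass for r in recs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(1, 2000), min_size=1, max_size=25, unique=True
        )
    )
    def test_cluster_matches_brute_force(self, positions):
        recs = [self._rec(p, FS=1.0, QD=20.0) for p in sorted(positions)]
        out = apply_site_filters(recs)
        expect = brute_force_cluster_flags(positions, 3, 35)
        got = {r.pos for r in out if "SnpCluster" in r.filter_flags}
        assert got == expect


class TestVcfRoundTrip:
    def test_records_survive_write_read(self, tmp_path, study):
        path = tmp_path / "out.vcf"
        write_vcf(path, study["somatic"], study["bundle"].contigs)
        back = read_vcf(path)
        assert [(r.chrom, r.pos, r.ref, r.alt) for r in back] == [
            (r.chrom, r.pos, r.ref, r.alt) for r in study["somatic"]
        ]
        assert all(
            abs(a.info["FS"] - b.info["FS"]) < 1e-4
            for a, b in zip(back, study["somatic"])
        )
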