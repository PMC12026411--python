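"""Motif algebra, catalog merging, windows and TR-representing indels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scetr.catalog import (
    CatalogError,
    TRLocus,
    assign_window,
    canonical_motif,
    is_tr_representing_indel,
    merge_catalogs,
    motif_rotations,
    read_bed,
    revcomp,
    write_bed,
)

motifs = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestCanonicalMotif:
    def test_triplet_class_enumeration(self):
        # GCA's class = rotations of GCA and of its revcomp TGC
        cls = {"AGC", "GCA", "CAG", "GCT", "CTG", "TGC"}
        for m in cls:
            assert canonical_motif(m) == "AGC"

    def test_reverse_complement_pairs_harmonize(self):
        assert canonical_motif("CAG") == canonical_motif("CTG")

    def test_palindromic_class(self):
        assert canonical_motif("AT") == "AT"

    def test_rejects_non_dna(self):
        with pytest.raises(CatalogError):
            canonical_motif("ACGN")
        with pytest.raises(CatalogError):
            canonical_motif("")

    @settings(max_examples=300, deadline=None)
    @given(motifs)
    def test_invariant_under_rotation_and_revcomp(self, m):
        rep = canonical_motif(m)
        for rot in motif_rotations(m):
            assert canonical_motif(rot) == rep
        assert canonical_motif(revcomp(m)) == rep

    @settings(max_examples=200, deadline=None)
    @given(motifs)
    def test_revcomp_involution(self, m):
        assert revcomp(revcomp(m)) == m

    @settings(max_examples=200, deadline=None)
    @given(motifs, motifs)
    def test_equivalence_relation_symmetry(self, a, b):
        # symmetric: a ~ b iff b ~ a (trivially via representative equality)
        assert (canonical_motif(a) == canonical_motif(b)) == (
            canonical_motif(b) == canonical_motif(a)
        )


class TestMergeCatalogs:
    def loc(self, start, end, motif="AC"):
        return TRLocus("chr1", start, end, motif)

    def test_identical_loci_deduplicated(self):
        a = [self.loc(100, 140)]
        b = [self.loc(100, 140)]
        assert merge_catalogs([a, b]) == [self.loc(100, 140)]

    def test_half_overlap_same_motif_both_retained(self):
        a = [self.loc(100, 200)]
        b = [self.loc(150, 250)]  # 50/100 = 50% < 66%
        assert len(merge_catalogs([a, b])) == 2

    def test_covered_candidate_same_motif_excluded(self):
        a = [self.loc(100, 200)]
        b = [self.loc(110, 190)]  # fully covered, same motif
        assert merge_catalogs([a, b]) == a

    def test_full_overlap_different_motif_class_both_retained(self):
        a = [self.loc(100, 140, "AC")]
        b = [self.loc(100, 140, "AG")]
        assert len(merge_catalogs([a, b])) == 2

    def test_motif_identity_uses_class(self):
        # GT is the revcomp of AC: same class, so the covered copy is dropped
        a = [self.loc(100, 140, "AC")]
        b = [self.loc(100, 140, "GT")]
        assert merge_catalogs([a, b]) == a

    def test_unsorted_input_rejected(self):
        with pytest.raises(CatalogError):
            merge_catalogs([[self.loc(200, 240), self.loc(100, 140)]])

    def test_idempotent(self):
        cats = [
            [self.loc(100, 200, "AC"), self.loc(400, 460, "AGC")],
            [self.loc(150, 250, "AC"), self.loc(400, 460, "AGG")],
        ]
        merged = merge_catalogs(cats)
        assert merge_catalogs([merged, merged]) == merged


class TestTrRepresentingIndel:
    locus = TRLocus("chr1", 1000, 1040, "AT")

    def test_whole_copy_deletion_inside_locus(self):
        assert is_tr_representing_indel((1010, "GATAT", "G"), self.locus)

    def test_partial_copy_insertion_retained(self):
        assert not is_tr_representing_indel((1010, "G", "GATA"), self.locus)

    def test_cyclic_rotation_counts(self):
        assert is_tr_representing_indel((1010, "G", "GTA"), self.locus)

    def test_outside_locus_interval(self):
        assert not is_tr_representing_indel((2000, "GATAT", "G"), self.locus)

    def test_substitution_rejected(self):
        with pytest.raises(CatalogError):
            is_tr_representing_indel((1010, "A", "T"), self.locus)

    @settings(max_examples=100, deadline=None)
    @given(st.sampled_from(["AT", "AGC", "AAGG"]), st.integers(1, 3),
           st.integers(0, 3))
    def test_invariant_under_motif_rotation(self, motif, copies, rot_i):
        locus = TRLocus("chr1", 1000, 1000 + 10 * len(motif), motif)
        seq = motif * copies
        indel = (1005, "G", "G" + seq)
        rotated = motif_rotations(motif)[rot_i % len(motif)]
        locus_rot = TRLocus("chr1", 1000, locus.end, rotated)
        assert is_tr_representing_indel(indel, locus) == is_tr_representing_indel(
            indel, locus_rot
        )


class TestAssignWindow:
    def test_boundary_inclusive(self):
        tss, tes = 500_000, 500_000
        inside = TRLocus("chr1", 400_000, 400_001, "A")  # at TSS - 100000
        outside = TRLocus("chr1", 399_999, 400_000, "A")  # ends at TSS - 100001
        got = assign_window((tss, tes), [inside, outside])
        assert got == [inside]

    def test_point_gene_flanking_counts(self):
        tss = tes = 1_000_000
        vs = [
            TRLocus("chr1", tss - 150_000, tss - 149_990, "A"),
            TRLocus("chr1", tss - 50_000, tss - 49_990, "A"),
            TRLocus("chr1", tss + 50_000, tss + 50_010, "A"),
            TRLocus("chr1", tss + 150_000, tss + 150_010, "A"),
        ]
        assert len(assign_window((tss, tes), vs)) == 2


def test_bed_roundtrip(tmp_path):
    loci = [TRLocus("chr1", 10, 30, "AC", 10.0), TRLocus("chr2", 5, 20, "AGC", 5.0)]
    path = tmp_path / "catalog.bed"
    write_bed(loci, path)
    assert read_bed(path) == loci
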