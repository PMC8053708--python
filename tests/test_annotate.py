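"""Reference builders, the aligner (against a brute-force oracle) and the
annotation cascade with tRNA-fragment typing."""

from __future__ import annotations

import numpy as np
import pytest

import srnachem.annotate as ann
from srnachem.annotate import (
    AnnotationHit,
    CascadeConfig,
    ReferenceDB,
    ReferenceRecord,
    align_read,
    annotate_cascade,
    build_mature_trna_refs,
    build_precursor_refs,
    classify_tsrna,
)

from conftest import brute_force_align

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


class TestMatureTrnaRefs:
    def test_cca_appended_and_his_g_prefixed(self):
        rng = np.random.default_rng(0)
        body = rand_seq(rng, 72)
        raw = [
            ReferenceRecord("t1", ann.CLASS_CYTO_TRNA, body, anticodon_span=(34, 36)),
            ReferenceRecord(
                "t2", ann.CLASS_CYTO_TRNA, body, anticodon_span=(33, 35), is_histidine=True
            ),
        ]
        mature = build_mature_trna_refs(raw)
        assert len(mature[0].sequence) == 75
        assert mature[0].sequence.endswith("CCA")
        assert mature[0].anticodon_span == (34, 36)
        assert len(mature[1].sequence) == 76
        assert mature[1].sequence.startswith("G")
        assert mature[1].anticodon_span == (34, 36)

    def test_cca_appended_even_if_already_present(self):
        raw = [
            ReferenceRecord(
                "t", ann.CLASS_CYTO_TRNA, "A" * 30 + "CCA", anticodon_span=(10, 12)
            )
        ]
        assert build_mature_trna_refs(raw)[0].sequence.endswith("CCACCA")

    def test_empty_input(self):
        assert build_mature_trna_refs([]) == []


class TestPrecursorRefs:
    def test_standard_window(self):
        rng = np.random.default_rng(1)
        contig = rand_seq(rng, 2000)
        [pre] = build_precursor_refs({"c": contig}, [("p1", "c", 1000, 1072)])
        assert len(pre.sequence) == 272
        assert pre.mature_span == (100, 172)
        assert pre.sequence == contig[900:1172]

    def test_clipped_at_contig_edge(self):
        rng = np.random.default_rng(1)
        contig = rand_seq(rng, 500)
        [pre] = build_precursor_refs({"c": contig}, [("p1", "c", 30, 102)])
        assert pre.sequence == contig[0:202]
        assert pre.mature_span == (30, 102)

    def test_missing_contig_errors(self):
        with pytest.raises(KeyError):
            build_precursor_refs({"c": "ACGT"}, [("p1", "nope", 0, 4)])


class TestAlignRead:
    def test_exact_substring_hit(self):
        rng = np.random.default_rng(2)
        ref = ReferenceRecord("r", ann.CLASS_RRNA, rand_seq(rng, 200))
        read = ref.sequence[50:75]
        hit = align_read(read, [ref])
        assert (hit.start, hit.mismatches) == (50, 0)

    def test_single_mismatch_hit(self):
        ref = ReferenceRecord("r", ann.CLASS_RRNA, "TTTTACGTACCTTTTT")
        hit = align_read("ACGTACGT", [ref])
        assert hit is not None and hit.mismatches == 1
        # Brute force confirms uniqueness of the best placement.
        assert brute_force_align("ACGTACGT", [ref]) == (1, 0, hit.start)

    def test_two_mismatches_everywhere_is_none(self):
        ref = ReferenceRecord("r", ann.CLASS_RRNA, "TTTTACGAACCTTTTT")
        read = "ACGTACGTGG"
        assert brute_force_align(read, [ref]) is None
        assert align_read(read, [ref]) is None

    def test_oracle_agreement_on_random_instances(self):
        """The seeded-index aligner must agree with the exhaustive Hamming
        scan on hit existence, mismatch count and the tie-broken choice."""
        rng = np.random.default_rng(42)
        refs = [
            ReferenceRecord(f"r{i}", ann.CLASS_RRNA, rand_seq(rng, int(rng.integers(60, 300))))
            for i in range(5)
        ]
        n_checked = 0
        for _ in range(400):
            kind = rng.integers(0, 4)
            if kind == 0:
                read = rand_seq(rng, int(rng.integers(15, 41)))
            else:
                ref = refs[rng.integers(len(refs))]
                ln = int(rng.integers(15, min(41, len(ref.sequence))))
                start = int(rng.integers(0, len(ref.sequence) - ln + 1))
                read = ref.sequence[start : start + ln]
                for _ in range(int(kind - 1)):  # 0, 1 or 2 substitutions
                    pos = int(rng.integers(ln))
                    read = read[:pos] + BASES[(BASES.index(read[pos]) + 1) % 4] + read[pos + 1 :]
            expected = brute_force_align(read, refs)
            got = align_read(read, refs)
            if expected is None:
                assert got is None
            else:
                mm, ri, start = expected
                assert got is not None
                assert (got.mismatches, got.ref_id, got.start) == (mm, refs[ri].ref_id, start)
            n_checked += 1
        assert n_checked == 400


class TestCascadePriority:
    def build_db(self):
        rng = np.random.default_rng(3)
        mir = "ACGTTGCAACGTGGATCAGGTA"  # 22 nt
        trna_body = rand_seq(rng, 20) + mir + rand_seq(rng, 30)
        refs = [
            ReferenceRecord("mir-1", ann.CLASS_MIRNA, mir),
            ReferenceRecord(
                "tRNA-1", ann.CLASS_CYTO_TRNA, trna_body + "CCA", anticodon_span=(34, 36)
            ),
            ReferenceRecord("chr", ann.CLASS_GENOME, rand_seq(rng, 300) + mir + rand_seq(rng, 50)),
        ]
        return ReferenceDB(refs), mir, trna_body

    def test_shared_sequence_goes_to_mirna_first(self):
        db, mir, _ = self.build_db()
        hit = ann.annotate_read(mir, db)
        assert hit.ref_class == ann.CLASS_MIRNA

    def test_length_gate_routes_long_read_to_trna(self):
        db, mir, trna_body = self.build_db()
        read30 = trna_body[12 : 12 + 30]  # contains the shared 22-mer
        assert mir in read30
        hit = ann.annotate_read(read30, db)
        assert hit.ref_class == ann.CLASS_CYTO_TRNA

    def test_one_mismatch_mirna_falls_through_to_genome(self):
        # The only references are the miRNA itself and a genome carrying it:
        # the zero-mismatch miRNA stage cannot accept the variant, so it
        # falls through to the genome stage.
        rng = np.random.default_rng(5)
        mir = "ACGTTGCAACGTGGATCAGGTA"
        db = ReferenceDB(
            [
                ReferenceRecord("mir-1", ann.CLASS_MIRNA, mir),
                ReferenceRecord(
                    "chr", ann.CLASS_GENOME, rand_seq(rng, 200) + mir + rand_seq(rng, 50)
                ),
            ]
        )
        variant = "T" + mir[1:] if mir[0] != "T" else "A" + mir[1:]
        hit = ann.annotate_read(variant, db)
        assert hit is not None and hit.ref_class == ann.CLASS_GENOME
        assert hit.mismatches == 1

    def test_pirna_length_gate(self):
        rng = np.random.default_rng(4)
        cluster = rand_seq(rng, 400)
        db = ReferenceDB([ReferenceRecord("piC", ann.CLASS_PIRNA, cluster)])
        read28 = cluster[100:128]
        assert ann.annotate_read(read28, db).ref_class == ann.CLASS_PIRNA
        read35 = cluster[100:135]  # outside the 24-32 gate
        assert ann.annotate_read(read35, db) is None


class TestCascadePartition:
    def test_every_read_lands_exactly_once(self, scenario, small_study):
        lib = small_study.libraries["CPA"]
        n_collapsed = len(lib.pre.collapsed)
        assert len(lib.hits) + len(lib.unannotated) == n_collapsed
        assert len({h.sequence for h in lib.hits}) == len(lib.hits)


class TestClassifyTsrna:
    REF = ReferenceRecord(
        "t", ann.CLASS_CYTO_TRNA, "A" * 76, anticodon_span=(34, 36)
    )  # loop spans 32-38 (1-based)

    def hit(self, start0, end1):
        return AnnotationHit("A" * (end1 - start0), ann.CLASS_CYTO_TRNA, "t", start0, 0)

    @pytest.mark.parametrize(
        "start0,end1,expected",
        [
            (0, 34, ann.TSRNA_HALF5),   # 1-34, ends in the loop
            (0, 20, ann.TSRNA_TRF5),    # 1-20, ends before the loop
            (33, 76, ann.TSRNA_HALF3),  # 34-76, starts in the loop, reaches CCA
            (39, 76, ann.TSRNA_TRF3),   # 40-76, starts after the loop
            (19, 50, ann.TSRNA_INTERNAL),
            (0, 76, ann.TSRNA_INTERNAL),  # full-length molecule fits no fragment type
        ],
    )
    def test_mature_rules(self, start0, end1, expected):
        assert classify_tsrna(self.hit(start0, end1), self.REF) == expected

    def test_precursor_rules(self):
        pre = ReferenceRecord(
            "p", ann.CLASS_PRE_TRNA, "A" * 272, mature_span=(100, 172)
        )
        leader = AnnotationHit("A" * 31, ann.CLASS_PRE_TRNA, "p", 59, 0)  # 60-90
        trailer = AnnotationHit("A" * 30, ann.CLASS_PRE_TRNA, "p", 170, 0)
        assert classify_tsrna(leader, pre) == ann.TSRNA_LEADER5
        assert classify_tsrna(trailer, pre) == ann.TSRNA_TRAILER3

    def test_missing_anticodon_errors(self):
        ref = ReferenceRecord("x", ann.CLASS_RRNA, "A" * 76)
        with pytest.raises(ValueError):
            classify_tsrna(self.hit(0, 20), ref)
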