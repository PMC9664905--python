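"""Domain-model behaviour: part construction, assembly sequences, idempotent
conversion."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from basicdna import config
from basicdna.collections import synthetic_bases, synthetic_part
from basicdna.core import (BasicAssembly, NucleotideSequence, SequenceFeature,
                           assembled_sequence, assembly_to_part, make_part,
                           min_rotation, reverse_complement)
from basicdna.errors import (AmbiguousSequenceError, InvalidSequenceError,
                             MissingBoundaryError, MissingFlankError,
                             MultipleBoundaryError)

from conftest import make_boundary, make_test_linker

IP, IS = config.DEFAULT_IP, config.DEFAULT_IS


class TestNucleotideSequence:
    def test_case_insensitive_normalization(self):
        assert NucleotideSequence("acgT").bases == "ACGT"
        assert NucleotideSequence("ACGT") == NucleotideSequence("acgt")

    @pytest.mark.parametrize("bad,exc", [
        ("ACGN", AmbiguousSequenceError),
        ("ACRT", AmbiguousSequenceError),
        ("ACG-", InvalidSequenceError),
        ("", InvalidSequenceError),
    ])
    def test_rejects_non_canonical(self, bad, exc):
        with pytest.raises(exc):
            NucleotideSequence(bad)

    def test_ambiguity_error_is_distinct(self):
        # IUPAC codes get the more specific error class
        assert issubclass(AmbiguousSequenceError, InvalidSequenceError)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reverse_complement_involution(self, bases):
        assert reverse_complement(reverse_complement(bases)) == bases

    def test_circular_equivalence_up_to_rotation(self):
        a = NucleotideSequence("ACGTTG", circular=True)
        b = NucleotideSequence("TTGACG", circular=True)
        assert a.equivalent(b)
        assert not a.equivalent(NucleotideSequence("ACGTTG", circular=False))

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30),
           st.integers(0, 29))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_min_rotation_is_rotation_invariant(self, bases, k):
        k %= len(bases)
        rotated = bases[k:] + bases[:k]
        assert min_rotation(bases) == min_rotation(rotated)


class TestMakePart:
    def test_length_additivity(self):
        raw = NucleotideSequence(synthetic_bases(200, 1))
        part = make_part(raw, "p", already_flanked=False)
        assert len(part.sequence.bases) == 200 + len(IP) + len(IS)

    def test_already_flanked_identity(self):
        raw = NucleotideSequence(IP + synthetic_bases(120, 2) + IS)
        part = make_part(raw, "p", already_flanked=True)
        assert part.sequence.bases == raw.bases

    def test_already_flanked_requires_flanks(self):
        with pytest.raises(MissingFlankError):
            make_part(NucleotideSequence(synthetic_bases(120, 3)), "p",
                      already_flanked=True)

    def test_feature_offset_matches_subsequence_search(self):
        # oracle: locate the feature's subsequence in the flanked part
        core = synthetic_bases(120, 4)
        feature = SequenceFeature("f", "misc_feature", 10, 20)
        part = make_part(NucleotideSequence(core), "p", features=[feature])
        motif = core[10:20]
        expected_start = part.sequence.bases.find(IP + core) + len(IP) + core.find(motif)
        assert part.features[0].start == expected_start == 10 + len(IP)
        assert part.features[0].end == expected_start + 10

    def test_core_round_trip(self):
        core = synthetic_bases(150, 5)
        part = make_part(NucleotideSequence(core), "p")
        assert part.core == core


class TestAssembledSequence:
    def test_single_part_length(self, lmp):
        # spec arithmetic: one 300 bp core + one 45 bp linker = 345 bp circle
        linker = dataclasses.replace(
            make_test_linker(5),
            sequence=NucleotideSequence(synthetic_bases(45, 6)))
        part = synthetic_part(300, 7, id="p300")
        seq, _ = assembled_sequence(BasicAssembly("a", (linker, part)))
        assert len(seq) == 345
        assert seq.circular

    def test_three_part_length_is_sum_of_cores_and_linkers(self, parts):
        cores = [synthetic_part(n, n, id=f"p{n}") for n in (300, 400, 500)]
        linkers = []
        for i in (1, 2, 3):
            l = make_test_linker(i)
            linkers.append(dataclasses.replace(
                l, sequence=NucleotideSequence(synthetic_bases(45, 100 + i))))
        elements = (linkers[0], cores[0], linkers[1], cores[1],
                    linkers[2], cores[2])
        seq, _ = assembled_sequence(BasicAssembly("a", elements))
        assert len(seq) == 300 + 400 + 500 + 3 * 45 == 1335

    def test_length_conservation_property(self, three_part_assembly):
        seq, _ = assembled_sequence(three_part_assembly)
        expected = sum(len(e.sequence.bases) if hasattr(e, "role") else len(e.core)
                       for e in three_part_assembly.elements)
        assert len(seq) == expected

    def test_core_features_carried_over_once(self):
        core = synthetic_bases(200, 8)
        part = make_part(NucleotideSequence(core), "p",
                         features=[SequenceFeature("gene1", "CDS", 20, 80)])
        linker = make_test_linker(1)
        seq, features = assembled_sequence(BasicAssembly("a", (linker, part)))
        assert len(features) == 1
        f = features[0]
        start = len(linker.sequence.bases) + 20
        assert (f.start, f.end, f.label) == (start, start + 60, "gene1")
        assert seq.bases[f.start:f.end] == core[20:80]

    def test_rotation_invariance(self, three_part_assembly):
        elements = three_part_assembly.elements
        rotated = BasicAssembly("rot", elements[2:] + elements[:2])
        seq_a, _ = assembled_sequence(three_part_assembly)
        seq_b, _ = assembled_sequence(rotated)
        assert seq_a.equivalent(seq_b)
        assert seq_a.bases != seq_b.bases  # genuinely different start points


class TestAssemblyToPart:
    def test_span_equals_payload_core(self, hierarchical_assembly, parts):
        new = assembly_to_part(hierarchical_assembly, "new")
        assert new.core == parts[0].core
        # brute-force oracle: substring of the assembled circle between the
        # LMP end and the LMS start
        seq, _ = assembled_sequence(hierarchical_assembly)
        lmp_len = len(hierarchical_assembly.elements[0].sequence.bases)
        lms_start = seq.bases.find(
            hierarchical_assembly.elements[2].sequence.bases, lmp_len)
        assert new.core == seq.bases[lmp_len:lms_start]

    def test_missing_boundary_raises(self, lmp, parts):
        a = BasicAssembly("a", (lmp, parts[0], make_test_linker(1), parts[1]))
        with pytest.raises(MissingBoundaryError):
            assembly_to_part(a, "new")

    def test_multiple_boundary_raises(self, lms, parts):
        lmp_a = make_boundary("boundary_LMP")
        lmp_b = dataclasses.replace(make_test_linker(55), role="boundary_LMP")
        a = BasicAssembly("a", (lmp_a, parts[0], lmp_b, parts[1],
                                lms, parts[2]))
        with pytest.raises(MultipleBoundaryError):
            assembly_to_part(a, "new")

    def test_idempotency_fixed_point(self, hierarchical_assembly, lmp, lms, parts):
        """Converting and re-assembling in the same backbone reproduces the
        original circle (up to rotation)."""
        new = assembly_to_part(hierarchical_assembly, "new")
        rebuilt = BasicAssembly("rebuilt", (lmp, new, lms, parts[1]))
        original, _ = assembled_sequence(hierarchical_assembly)
        again, _ = assembled_sequence(rebuilt)
        assert original.equivalent(again)

    def test_multi_element_span(self, lmp, lms, parts):
        """The derived core spans every element between LMP and LMS."""
        mid = make_test_linker(7)
        a = BasicAssembly("a", (lmp, parts[0], mid, parts[2], lms, parts[1]))
        new = assembly_to_part(a, "new")
        assert new.core == (parts[0].core + mid.sequence.bases + parts[2].core)
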