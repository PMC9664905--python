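"""Build planning: clip deduplication, mass arithmetic, multiplicities."""

import random

import pytest
from Bio.SeqUtils import molecular_weight

from basicdna.build import (assemblies_from_build, builds_equal,
                            clip_multiplicity, compute_build,
                            ds_molecular_weight, part_mass)
from basicdna.collections import synthetic_part
from basicdna.core import BasicAssembly
from basicdna.errors import BuildConsistencyError, ParameterError

from conftest import make_test_linker


class TestMolecularWeight:
    def test_matches_biopython_dsdna_model(self):
        """Independent cross-check: Biopython computes the same duplex
        weight from atomic composition."""
        for seed, n in ((1, 100), (2, 537), (3, 1000)):
            bases = synthetic_part(n, seed).sequence.bases
            ours = ds_molecular_weight(bases)
            ref = molecular_weight(bases, "DNA", double_stranded=True)
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_hand_calculated_1000bp_part(self):
        # arithmetic oracle: 250 of each base per strand, both strands
        bases = "ATCG" * 250
        per_strand = 250 * (331.2218 + 322.2085 + 307.1971 + 347.2212)
        expected = 2 * (per_strand - 999 * 18.0153)
        assert ds_molecular_weight(bases) == pytest.approx(expected, rel=1e-12)
        mass = part_mass(bases)
        assert mass == pytest.approx(2.5e-9 * 30e-6 * expected * 1e9, rel=1e-12)


class TestPartMass:
    def test_volume_linearity(self):
        bases = synthetic_part(500, 4).sequence.bases
        assert part_mass(bases, reaction_volume_l=60e-6) == pytest.approx(
            2 * part_mass(bases, reaction_volume_l=30e-6), rel=1e-12)

    def test_concentration_inversion(self):
        """mass / (MW x volume) recovers 2.5 nM to machine precision."""
        for seed in range(5):
            part = synthetic_part(200 + 150 * seed, 40 + seed)
            bases = part.sequence.bases
            mass_ng = part_mass(bases)
            conc = mass_ng * 1e-9 / (ds_molecular_weight(bases) * 30e-6)
            assert conc == pytest.approx(2.5e-9, rel=1e-12)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ParameterError):
            part_mass("ACGT", reaction_volume_l=0)
        with pytest.raises(ParameterError):
            part_mass("ACGT", final_conc_m=-1e-9)


class TestClipMultiplicity:
    @pytest.mark.parametrize("total,capacity,expected",
                             [(15, 15, 1), (16, 15, 2), (45, 15, 3), (1, 15, 1)])
    def test_ceiling(self, total, capacity, expected):
        assert clip_multiplicity(total, capacity) == expected

    def test_exhaustive_against_iterative_subtraction(self):
        for total in range(1, 101):
            remaining, count = total, 0
            while remaining > 0:
                remaining -= 15
                count += 1
            assert clip_multiplicity(total, 15) == count

    def test_monotonicity(self):
        for total in range(1, 60):
            assert (clip_multiplicity(total + 1, 15)
                    >= clip_multiplicity(total, 15))
            assert (clip_multiplicity(total, 16)
                    <= clip_multiplicity(total, 15))

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            clip_multiplicity(0, 15)
        with pytest.raises(ParameterError):
            clip_multiplicity(10, 0)


def _pools():
    linkers = [make_test_linker(i) for i in range(8)]
    parts = [synthetic_part(150 + 10 * i, 7000 + i, id=f"BP{i}")
             for i in range(6)]
    return linkers, parts


def _random_assembly(rng, name, linkers, parts):
    n = rng.randint(1, 4)
    chosen_linkers = rng.sample(linkers, n)
    chosen_parts = [rng.choice(parts) for _ in range(n)]
    elements = []
    for l, p in zip(chosen_linkers, chosen_parts):
        elements += [l, p]
    return BasicAssembly(name, tuple(elements))


class TestComputeBuild:
    def test_single_assembly_three_clips(self, three_part_assembly):
        build = compute_build([three_part_assembly])
        assert len(build.clips_data) == 3
        assert all(c.total_assemblies == 1 for c in build.clips_data.values())
        assert len(build.unique_parts) == 3
        assert len(build.unique_linkers) == 3

    def test_identical_assemblies_share_clips(self, three_part_assembly):
        twin = BasicAssembly("twin", three_part_assembly.elements)
        build = compute_build([three_part_assembly, twin])
        assert len(build.clips_data) == 3
        assert all(c.total_assemblies == 2 for c in build.clips_data.values())

    def test_dedup_matches_brute_force_oracle(self):
        """Unique clip count equals the direct set of (prefix, part, suffix)
        identity triples over randomized builds of up to 50 assemblies."""
        linkers, parts = _pools()
        rng = random.Random(11)
        for trial in range(5):
            assemblies = [_random_assembly(rng, f"a{trial}_{i}", linkers, parts)
                          for i in range(rng.randint(1, 50))]
            build = compute_build(assemblies)
            brute = set()
            for a in assemblies:
                n = len(a.elements)
                for i, e in enumerate(a.elements):
                    if hasattr(e, "role"):
                        continue
                    pre = a.elements[(i - 1) % n]
                    suf = a.elements[(i + 1) % n]
                    brute.add(((pre.id, pre.sequence.bases),
                               (e.id, e.sequence.bases),
                               (suf.id, suf.sequence.bases)))
            assert len(build.clips_data) == len(brute)

    def test_clip_conservation(self):
        linkers, parts = _pools()
        rng = random.Random(12)
        assemblies = [_random_assembly(rng, f"a{i}", linkers, parts)
                      for i in range(20)]
        build = compute_build(assemblies)
        total_usages = sum(c.total_assemblies for c in build.clips_data.values())
        assert total_usages == sum(len(a.parts) for a in assemblies)

    def test_dedup_idempotence(self):
        linkers, parts = _pools()
        rng = random.Random(13)
        assemblies = [_random_assembly(rng, f"a{i}", linkers, parts)
                      for i in range(10)]
        build = compute_build(assemblies)
        rebuilt = compute_build(assemblies_from_build(build))
        assert builds_equal(build, rebuilt)

    def test_key_assignment_deterministic(self):
        linkers, parts = _pools()
        rng = random.Random(14)
        assemblies = [_random_assembly(rng, f"a{i}", linkers, parts)
                      for i in range(10)]
        b1 = compute_build(assemblies)
        b2 = compute_build(assemblies)
        assert list(b1.clips_data) == list(b2.clips_data)
        assert builds_equal(b1, b2)

    def test_duplicate_assembly_ids_rejected(self, three_part_assembly):
        twin = BasicAssembly(three_part_assembly.id,
                             three_part_assembly.elements)
        with pytest.raises(BuildConsistencyError, match="duplicate assembly"):
            compute_build([three_part_assembly, twin])

    def test_same_id_different_sequence_rejected(self):
        l1, l2, l3, l4 = (make_test_linker(i) for i in range(4))
        p_a = synthetic_part(150, 1, id="P")
        p_b = synthetic_part(150, 2, id="P")  # same id, different bases
        a1 = BasicAssembly("a1", (l1, p_a, l2, synthetic_part(150, 3, id="Q")))
        a2 = BasicAssembly("a2", (l3, p_b, l4, synthetic_part(150, 3, id="Q")))
        with pytest.raises(BuildConsistencyError, match="share id"):
            compute_build([a1, a2])

    def test_invalid_assembly_rejected_with_names(self, parts):
        bad = BasicAssembly("broken", (make_test_linker(1), parts[0],
                                       make_test_linker(2)))
        with pytest.raises(BuildConsistencyError, match="broken"):
            compute_build([bad])

    def test_part_mass_on_storage_format(self, three_part_assembly):
        build = compute_build([three_part_assembly])
        for clip in build.clips_data.values():
            bases = build.unique_parts[clip.part].sequence.bases
            assert clip.part_mass_ng == pytest.approx(part_mass(bases))
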