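"""Shared fixtures: deterministic synthetic linkers and parts.

All sequences come from the package's seeded generator, so every test run
sees identical inputs.  Helper factories return *distinct* linkers (unique
ids and half identities) unless a test explicitly asks for a clash.
"""

import pytest

from basicdna.collections import synthetic_bases, synthetic_part
from basicdna.core import BasicAssembly, BasicLinker, LinkerHalf, NucleotideSequence


def make_test_linker(i: int, role: str = "neutral",
                     prefix_half_id: str | None = None,
                     suffix_half_id: str | None = None) -> BasicLinker:
    """Deterministic neutral/functional linker with 24 bp halves."""
    pre_id = prefix_half_id or f"L{i}-P"
    suf_id = suffix_half_id or f"L{i}-S"
    pre = synthetic_bases(24, 1000 + 7 * i)
    suf = synthetic_bases(24, 2000 + 7 * i)
    return BasicLinker(
        id=f"L{i}", sequence=NucleotideSequence(pre + suf),
        prefix_half=LinkerHalf(pre_id, NucleotideSequence(pre), "prefix"),
        suffix_half=LinkerHalf(suf_id, NucleotideSequence(suf), "suffix"),
        role=role)


def make_boundary(role: str) -> BasicLinker:
    i = 90 if role == "boundary_LMP" else 91
    linker = make_test_linker(i, role=role)
    name = "LMP" if role == "boundary_LMP" else "LMS"
    return BasicLinker(id=name, sequence=linker.sequence,
                       prefix_half=LinkerHalf(f"{name}-P", linker.prefix_half.sequence, "prefix"),
                       suffix_half=LinkerHalf(f"{name}-S", linker.suffix_half.sequence, "suffix"),
                       role=role, methylated=True)


@pytest.fixture(scope="session")
def lmp() -> BasicLinker:
    return make_boundary("boundary_LMP")


@pytest.fixture(scope="session")
def lms() -> BasicLinker:
    return make_boundary("boundary_LMS")


@pytest.fixture(scope="session")
def parts():
    """Five clean 150-500 bp parts, P0..P4."""
    return [synthetic_part(150 + 50 * i, 4242 + i, id=f"P{i}") for i in range(5)]


@pytest.fixture
def three_part_assembly(parts):
    """A valid 3-part / 3-linker circle (no boundary linkers)."""
    l1, l2, l3 = (make_test_linker(i) for i in (1, 2, 3))
    return BasicAssembly("triple", (l1, parts[0], l2, parts[1], l3, parts[2]))


@pytest.fixture
def hierarchical_assembly(lmp, lms, parts):
    """LMP / payload / LMS / backbone — convertible to a next-tier part."""
    return BasicAssembly("tiered", (lmp, parts[0], lms, parts[1]))
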