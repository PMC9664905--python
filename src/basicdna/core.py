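"""Domain model for BASIC DNA assembly.

BASIC (Biopart Assembly Standard for Idempotent Cloning) composes circular
constructs from alternating *parts* and *linkers*.  Parts are kept in a
single storage format — core sequence flanked by the integrated prefix (iP)
and suffix (iS), each carrying a BsaI site — so that a clip reaction excises
the core and ligates linker halves to it.  An assembly whose interior is
flanked by the methylated LMP/LMS boundary linkers reconstitutes the storage
format, which is what makes the method idempotent: assemblies are themselves
parts for the next tier.

This module holds the value types (:class:`NucleotideSequence`,
:class:`SequenceFeature`, :class:`BasicPart`, :class:`LinkerHalf`,
:class:`BasicLinker`, :class:`BasicAssembly`) and the sequence-level
operations: building parts (:func:`make_part`), computing the assembled
circular sequence with features carried over (:func:`assembled_sequence`),
and the idempotent conversion back to a part (:func:`assembly_to_part`).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence, Union

from . import config
from .errors import (
    AmbiguousSequenceError,
    FeatureBoundsError,
    InvalidSequenceError,
    MissingBoundaryError,
    MissingFlankError,
    MultipleBoundaryError,
)

_CANONICAL = frozenset("ACGT")
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

LinkerRole = Literal["boundary_LMP", "boundary_LMS", "neutral", "functional"]
HalfSide = Literal["prefix", "suffix"]


def reverse_complement(bases: str) -> str:
    """Reverse complement of an upper-case ACGT string."""
    return bases.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def min_rotation(bases: str) -> str:
    """Lexicographically minimal rotation; the canonical form used for
    comparing circular sequences."""
    doubled = bases + bases
    best = min(doubled[i:i + len(bases)] for i in range(len(bases)))
    return best


@dataclasses.dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over {A, C, G, T}, linear or circular.

    Bases are upper-cased on construction, so equality and deduplication are
    case-insensitive.  IUPAC ambiguity codes are rejected with
    :class:`AmbiguousSequenceError`; anything else non-ACGT with
    :class:`InvalidSequenceError`.
    """

    bases: str
    circular: bool = False

    def __post_init__(self) -> None:
        norm = self.bases.upper()
        if not norm:
            raise InvalidSequenceError("empty sequence")
        letters = set(norm)
        if not letters <= _CANONICAL:
            bad = letters - _CANONICAL
            if bad <= _IUPAC_AMBIGUOUS:
                raise AmbiguousSequenceError(
                    f"IUPAC ambiguity codes not supported: {sorted(bad)}")
            raise InvalidSequenceError(f"non-DNA characters: {sorted(bad)}")
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(reverse_complement(self.bases), self.circular)

    def canonical(self) -> str:
        """Rotation-canonical bases for circular sequences, bases otherwise."""
        return min_rotation(self.bases) if self.circular else self.bases

    def equivalent(self, other: "NucleotideSequence") -> bool:
        """Equality up to rotation for circular sequences."""
        if self.circular != other.circular:
            return False
        return self.canonical() == other.canonical()


@dataclasses.dataclass(frozen=True)
class SequenceFeature:
    """An annotated span, 0-based half-open, on a parent sequence.

    ``kind`` mirrors GenBank feature keys (``CDS``, ``promoter``,
    ``misc_feature``...).  Features may wrap the origin only on circular
    parents, represented by ``end > parent length``.
    """

    label: str
    kind: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise FeatureBoundsError(f"strand must be +1/-1, got {self.strand}")
        if not (0 <= self.start < self.end):
            raise FeatureBoundsError(
                f"need 0 <= start < end, got [{self.start}, {self.end})")

    def shifted(self, offset: int) -> "SequenceFeature":
        return dataclasses.replace(self, start=self.start + offset,
                                   end=self.end + offset)

    def check_bounds(self, parent_length: int, circular: bool = False) -> None:
        limit = parent_length * 2 if circular else parent_length
        if self.start >= parent_length or self.end > limit:
            raise FeatureBoundsError(
                f"feature [{self.start}, {self.end}) outside parent of "
                f"length {parent_length} ({'circular' if circular else 'linear'})")


@dataclasses.dataclass(frozen=True)
class BasicPart:
    """A DNA part in BASIC storage format: iP + core + iS, annotated.

    Feature coordinates refer to the storage sequence (flanks included).
    """

    id: str
    sequence: NucleotideSequence
    features: tuple[SequenceFeature, ...] = ()
    description: str = ""
    ip: str = config.DEFAULT_IP
    is_: str = config.DEFAULT_IS

    def __post_init__(self) -> None:
        if self.sequence.circular:
            raise InvalidSequenceError(
                f"part {self.id!r}: storage format is linear")
        bases = self.sequence.bases
        if not (bases.startswith(self.ip) and bases.endswith(self.is_)):
            raise MissingFlankError(
                f"part {self.id!r}: sequence must start with iP and end with iS")
        if len(bases) < len(self.ip) + len(self.is_) + 1:
            raise MissingFlankError(f"part {self.id!r}: empty core")
        object.__setattr__(self, "features", tuple(self.features))
        for f in self.features:
            f.check_bounds(len(bases))

    @property
    def core(self) -> str:
        """Sequence with the iP/iS flanks removed."""
        return self.sequence.bases[len(self.ip):len(self.sequence.bases) - len(self.is_)]

    def core_features(self) -> tuple[SequenceFeature, ...]:
        """Features fully inside the core, re-based to core coordinates."""
        lo, hi = len(self.ip), len(self.sequence.bases) - len(self.is_)
        return tuple(f.shifted(-lo) for f in self.features
                     if lo <= f.start and f.end <= hi)


@dataclasses.dataclass(frozen=True)
class LinkerHalf:
    """One side of a linker: an identity label plus its sequence.

    Halves sharing an identity label (e.g. the same UTR) must share a
    sequence; this is what makes half-identity clashes detectable before
    the bench.
    """

    half_id: str
    sequence: NucleotideSequence
    side: HalfSide

    def __post_init__(self) -> None:
        if self.side not in ("prefix", "suffix"):
            raise InvalidSequenceError(f"half side must be prefix/suffix, got {self.side!r}")

    @property
    def identity(self) -> str:
        """Label used for clash detection; falls back to the sequence."""
        return self.half_id or self.sequence.bases


@dataclasses.dataclass(frozen=True)
class BasicLinker:
    """A named linker: full duplex sequence plus its prefix/suffix halves.

    ``role`` distinguishes the unique LMP/LMS boundary linkers (which carry
    methylated BsaI sites and define the next-tier part span) from neutral
    and functional (RBS- or fusion-encoding) linkers.
    """

    id: str
    sequence: NucleotideSequence
    prefix_half: LinkerHalf
    suffix_half: LinkerHalf
    role: LinkerRole = "neutral"
    methylated: bool = False

    def __post_init__(self) -> None:
        if self.prefix_half.side != "prefix":
            raise InvalidSequenceError(f"linker {self.id!r}: prefix half has side "
                                       f"{self.prefix_half.side!r}")
        if self.suffix_half.side != "suffix":
            raise InvalidSequenceError(f"linker {self.id!r}: suffix half has side "
                                       f"{self.suffix_half.side!r}")


def make_linker(id: str, prefix_bases: str, suffix_bases: str,
                prefix_half_id: str = "", suffix_half_id: str = "",
                role: LinkerRole = "neutral", methylated: bool = False) -> BasicLinker:
    """Convenience constructor: full sequence is the two halves concatenated."""
    return BasicLinker(
        id=id,
        sequence=NucleotideSequence(prefix_bases + suffix_bases),
        prefix_half=LinkerHalf(prefix_half_id or f"{id}-P",
                               NucleotideSequence(prefix_bases), "prefix"),
        suffix_half=LinkerHalf(suffix_half_id or f"{id}-S",
                               NucleotideSequence(suffix_bases), "suffix"),
        role=role,
        methylated=methylated,
    )


Element = Union[BasicLinker, BasicPart]


@dataclasses.dataclass(frozen=True)
class BasicAssembly:
    """An ordered, circular, alternating linker/part design.

    The element list begins with a linker and is implicitly circular (the
    last part wraps round to the first linker).  Structural invariants —
    alternation, balance, linker uniqueness, half compatibility — are the
    business of :func:`basicdna.validate.check_assembly`; they are stored
    unchecked here so invalid designs can be represented and reported on.
    """

    id: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.elements:
            raise InvalidSequenceError(f"assembly {self.id!r}: no elements")

    @property
    def linkers(self) -> tuple[BasicLinker, ...]:
        return tuple(e for e in self.elements if isinstance(e, BasicLinker))

    @property
    def parts(self) -> tuple[BasicPart, ...]:
        return tuple(e for e in self.elements if isinstance(e, BasicPart))

    @classmethod
    def checked(cls, id: str, elements: Iterable[Element]) -> "BasicAssembly":
        """Eagerly validated constructor; raises
        :class:`~basicdna.errors.AssemblyValidationError` on any error-severity
        issue."""
        from .validate import raise_on_errors  # local import: avoid cycle
        a = cls(id, tuple(elements))
        raise_on_errors(a)
        return a


def make_part(raw: NucleotideSequence, id: str,
              features: Sequence[SequenceFeature] = (),
              already_flanked: bool = False,
              description: str = "",
              ip: str = config.DEFAULT_IP,
              is_: str = config.DEFAULT_IS) -> BasicPart:
    """Build a storage-format part from a raw linear sequence.

    When ``already_flanked`` is false the iP/iS flanks are added and feature
    coordinates are shifted by ``len(ip)``; when true the input must already
    carry both flanks and is taken verbatim.
    """
    if raw.circular:
        raise InvalidSequenceError(f"part {id!r}: input must be linear")
    if already_flanked:
        if not (raw.bases.startswith(ip) and raw.bases.endswith(is_)):
            raise MissingFlankError(
                f"part {id!r}: already_flanked but iP/iS flanks absent")
        stored = raw.bases
        shifted = tuple(features)
    else:
        stored = ip + raw.bases + is_
        shifted = tuple(f.shifted(len(ip)) for f in features)
    return BasicPart(id=id, sequence=NucleotideSequence(stored),
                     features=shifted, description=description, ip=ip, is_=is_)


def _element_contribution(e: Element) -> str:
    return e.core if isinstance(e, BasicPart) else e.sequence.bases


def assembled_sequence(a: BasicAssembly,
                       validate: bool = True) -> tuple[NucleotideSequence,
                                                       tuple[SequenceFeature, ...]]:
    """Circular assembled sequence plus carried-over features.

    The model is linker full sequence followed by the next part's core, in
    element order, rotation canonicalized to start at element 0's first base.
    Part features fully inside the core are carried over; features on linkers
    are represented as one ``misc_feature``-free span per linker only in
    GenBank export, not here.
    """
    if validate:
        from .validate import raise_on_errors
        raise_on_errors(a)
    chunks: list[str] = []
    features: list[SequenceFeature] = []
    offset = 0
    for e in a.elements:
        chunk = _element_contribution(e)
        if isinstance(e, BasicPart):
            features.extend(f.shifted(offset) for f in e.core_features())
        chunks.append(chunk)
        offset += len(chunk)
    return NucleotideSequence("".join(chunks), circular=True), tuple(features)


def _boundary_index(a: BasicAssembly, role: LinkerRole) -> int:
    hits = [i for i, e in enumerate(a.elements)
            if isinstance(e, BasicLinker) and e.role == role]
    if not hits:
        raise MissingBoundaryError(
            f"assembly {a.id!r}: no {role} linker present")
    if len(hits) > 1:
        raise MultipleBoundaryError(
            f"assembly {a.id!r}: {role} linker occurs {len(hits)} times")
    return hits[0]


def assembly_to_part(a: BasicAssembly, new_id: str,
                     ip: str = config.DEFAULT_IP,
                     is_: str = config.DEFAULT_IS) -> BasicPart:
    """Idempotent conversion: the LMP/LMS-flanked span becomes a new part.

    The new core is the assembled sequence traversed forward from the end of
    the single LMP linker to the start of the single LMS linker (cyclically),
    re-flanked with iP/iS.  Features of parts wholly inside the span are
    preserved.
    """
    from .validate import raise_on_errors
    raise_on_errors(a)
    lmp = _boundary_index(a, "boundary_LMP")
    _boundary_index(a, "boundary_LMS")  # existence/uniqueness check
    n = len(a.elements)
    chunks: list[str] = []
    features: list[SequenceFeature] = []
    offset = 0
    for step in range(1, n):
        e = a.elements[(lmp + step) % n]
        if isinstance(e, BasicLinker) and e.role == "boundary_LMS":
            break
        chunk = _element_contribution(e)
        if isinstance(e, BasicPart):
            features.extend(f.shifted(offset) for f in e.core_features())
        chunks.append(chunk)
        offset += len(chunk)
    core = "".join(chunks)
    if not core:
        raise MissingBoundaryError(
            f"assembly {a.id!r}: LMP and LMS are adjacent; empty span")
    return make_part(NucleotideSequence(core), new_id, features=features,
                     already_flanked=False, ip=ip, is_=is_,
                     description=f"derived from assembly {a.id}")
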