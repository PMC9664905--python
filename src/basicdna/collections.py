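"""Versioned part/linker collections, synthetic fixtures and the SEVA designer.

The shipped collections reproduce the documented structure of the BASIC
ecosystem — a 65-linker commercial set (with 81 derivable UTR/RBS half
combinations), 60 insulated promoter parts, a 10-entry CDS set and the
30-vector BASIC SEVA collection — using structured synthetic placeholder
sequences.  Real catalogue sequences are proprietary; every placeholder
carries the correct id, role and half identities, and users can substitute
real sequences by registering their own collection version.

Placeholder sequences are synthesized deterministically at load time from a
code-level manifest (per-entry seed = CRC32 of ``collection:id``), so the
package ships no sequence data files yet always produces identical
collections.  Every synthetic core begins and ends with ``A``: neither BsaI
motif (GGTCTC / GAGACC) contains ``AA``, so concatenating such cores and
linkers can never create a restriction site across a junction.
"""

from __future__ import annotations

import dataclasses
import re
import zlib
from typing import Mapping, Sequence, Union

import numpy as np

from . import config
from .core import (BasicAssembly, BasicLinker, BasicPart, LinkerHalf,
                   NucleotideSequence, make_part)
from .errors import BasicDnaError, ParameterError, UnknownCollectionError
from .validate import check_part, find_bsai_sites, raise_on_errors

DEFAULT_FORBIDDEN_MOTIFS = (config.BSAI_SITE, config.BSAI_SITE_RC)

_BASES = np.array(list("ACGT"))


def _entry_seed(collection: str, entry_id: str) -> int:
    return zlib.crc32(f"{collection}:{entry_id}".encode()) & 0x7FFFFFFF


def synthetic_bases(length: int, seed: int,
                    forbid: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS) -> str:
    """Reproducible pseudo-random DNA of ``length`` bp, free of the
    forbidden motifs on both strands, starting and ending with ``A``."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    longest = max((len(m) for m in forbid), default=0)
    if length <= 2 and any(m in "A" * length for m in forbid):
        raise ParameterError("forbidden motifs make this length infeasible")
    rng = np.random.default_rng(seed)
    inner = max(length - 2, 0)
    for _ in range(1000):
        middle = "".join(_BASES[rng.integers(0, 4, inner)])
        bases = ("A" + middle + "A")[:length] if length > 1 else "A"
        if not any(m in bases for m in forbid):
            return bases
        # resample only the offending windows rather than the whole string
        chars = list(bases)
        for _ in range(200):
            dirty = False
            for m in forbid:
                start = "".join(chars).find(m)
                while start != -1:
                    dirty = True
                    for i in range(max(start, 1),
                                   min(start + len(m), length - 1)):
                        chars[i] = str(_BASES[rng.integers(0, 4)])
                    start = "".join(chars).find(m, start + 1)
            if not dirty:
                return "".join(chars)
    raise ParameterError(
        f"could not generate {length} bp avoiding {list(forbid)}")


def synthetic_part(length_bp: int, seed: int,
                   forbid: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
                   id: str | None = None, description: str = "",
                   ip: str = config.DEFAULT_IP,
                   is_: str = config.DEFAULT_IS) -> BasicPart:
    """A reproducible synthetic storage-format part with a clean
    ``length_bp`` core; identical seeds give identical parts."""
    core = synthetic_bases(length_bp, seed, forbid)
    part = make_part(NucleotideSequence(core),
                     id or f"SYN_{length_bp}_{seed}",
                     already_flanked=False, description=description,
                     ip=ip, is_=is_)
    flagged = [i for i in check_part(part, min_length=0)]
    if flagged:  # unreachable by construction; guards future motif sets
        raise BasicDnaError(f"synthetic part not clean: {flagged}")
    return part


def _synthetic_half(collection: str, half_id: str, side: str,
                    length: int = 26) -> LinkerHalf:
    bases = synthetic_bases(length, _entry_seed(collection, f"half:{half_id}:{side}"))
    return LinkerHalf(half_id, NucleotideSequence(bases), side)  # type: ignore[arg-type]


def _synthetic_linker(collection: str, id: str, role: str = "neutral",
                      methylated: bool = False,
                      prefix_half_id: str | None = None,
                      suffix_half_id: str | None = None) -> BasicLinker:
    prefix = _synthetic_half(collection, prefix_half_id or f"{id}-P", "prefix")
    if role == "boundary_LMP":
        # the 3' half of LMP carries the iP sequence it regenerates
        pad = synthetic_bases(8, _entry_seed(collection, f"half:{id}-S:pad"))
        suffix = LinkerHalf(suffix_half_id or f"{id}-S",
                            NucleotideSequence(pad + config.DEFAULT_IP),
                            "suffix")
    else:
        suffix = _synthetic_half(collection, suffix_half_id or f"{id}-S", "suffix")
    if role == "boundary_LMS":
        pad = synthetic_bases(8, _entry_seed(collection, f"half:{id}-P:pad"))
        prefix = LinkerHalf(prefix_half_id or f"{id}-P",
                            NucleotideSequence(config.DEFAULT_IS + pad),
                            "prefix")
    return BasicLinker(
        id=id,
        sequence=NucleotideSequence(prefix.sequence.bases + suffix.sequence.bases),
        prefix_half=prefix, suffix_half=suffix,
        role=role, methylated=methylated)  # type: ignore[arg-type]


Entry = Union[BasicPart, BasicLinker]


@dataclasses.dataclass(frozen=True)
class PartLinkerCollection:
    """A named, versioned set of parts and/or linkers with entry metadata."""

    name: str
    version: str
    entries: Mapping[str, Entry]
    metadata: Mapping[str, Mapping[str, str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, entry_id: str) -> Entry:
        return self.entries[entry_id]

    def parts(self) -> list[BasicPart]:
        return [e for e in self.entries.values() if isinstance(e, BasicPart)]

    def linkers(self) -> list[BasicLinker]:
        return [e for e in self.entries.values() if isinstance(e, BasicLinker)]


# --- the commercial linker set (structured placeholders) -------------------

_N_NEUTRAL = 18
_N_FUSION = 18
_N_UTRS = 3
_RBS_PER_UTR = 9  # 27 RBS suffix identities over 3 UTR prefix identities


def _biolegio_linkers() -> PartLinkerCollection:
    """65 linkers: LMP + LMS, 18 neutral, 18 fusion, 27 UTR/RBS.

    UTR/RBS linkers share one prefix half per UTR identity (3) and carry 27
    distinct RBS suffix-half identities, so 3 x 27 = 81 UTR/RBS half
    combinations are derivable from the labelled subset.
    """
    name = "BASIC_BIOLEGIO_LINKERS"
    entries: dict[str, Entry] = {}
    meta: dict[str, dict[str, str]] = {}

    for lid, role in (("LMP", "boundary_LMP"), ("LMS", "boundary_LMS")):
        entries[lid] = _synthetic_linker(name, lid, role=role, methylated=True)
        meta[lid] = {"category": "boundary"}
    for i in range(1, _N_NEUTRAL + 1):
        lid = f"L{i}"
        entries[lid] = _synthetic_linker(name, lid, role="neutral")
        meta[lid] = {"category": "neutral"}
    for i in range(1, _N_FUSION + 1):
        lid = f"LF{i}"
        entries[lid] = _synthetic_linker(name, lid, role="functional")
        meta[lid] = {"category": "fusion"}
    rbs = 0
    for u in range(1, _N_UTRS + 1):
        for _ in range(_RBS_PER_UTR):
            rbs += 1
            lid = f"UTR{u}-RBS{rbs:02d}"
            entries[lid] = _synthetic_linker(
                name, lid, role="functional",
                prefix_half_id=f"UTR{u}", suffix_half_id=f"RBS{rbs:02d}")
            meta[lid] = {"category": "utr_rbs", "utr": f"UTR{u}",
                         "rbs": f"RBS{rbs:02d}"}
    return PartLinkerCollection(name, "0.1", entries, meta)


def utr_rbs_combinations(collection: PartLinkerCollection) -> set[tuple[str, str]]:
    """All (UTR prefix-half, RBS suffix-half) identity pairs derivable from
    the labelled UTR/RBS subset of a linker collection."""
    utrs = {l.prefix_half.identity
            for lid, l in collection.entries.items()
            if collection.metadata.get(lid, {}).get("category") == "utr_rbs"
            and isinstance(l, BasicLinker)}
    rbss = {l.suffix_half.identity
            for lid, l in collection.entries.items()
            if collection.metadata.get(lid, {}).get("category") == "utr_rbs"
            and isinstance(l, BasicLinker)}
    return {(u, r) for u in sorted(utrs) for r in sorted(rbss)}


# --- promoter and CDS parts ------------------------------------------------

def _promoter_parts() -> PartLinkerCollection:
    name = "BASIC_PROMOTER_PARTS"
    entries: dict[str, Entry] = {}
    meta: dict[str, dict[str, str]] = {}
    for i in range(1, 61):
        pid = f"BP{i:02d}_Promoter"
        entries[pid] = synthetic_part(
            300, _entry_seed(name, pid), id=pid,
            description="insulated promoter (upstream terminator + promoter "
                        "+ RiboJ), synthetic placeholder")
        meta[pid] = {"category": "promoter"}
    return PartLinkerCollection(name, "0.1", entries, meta)


_CDS_NAMES = ("sfGFP", "mScarlet", "mCherry", "mTagBFP", "mVenus",
              "lacZ_alpha", "araC", "tetR", "lacI", "luxR")


def _cds_parts() -> PartLinkerCollection:
    name = "BASIC_CDS_PARTS"
    entries: dict[str, Entry] = {}
    meta: dict[str, dict[str, str]] = {}
    for cds in _CDS_NAMES:
        pid = f"BASIC_{cds}_CDS"
        entries[pid] = synthetic_part(
            720, _entry_seed(name, pid), id=pid,
            description=f"{cds} coding sequence, synthetic placeholder")
        meta[pid] = {"category": "cds"}
    return PartLinkerCollection(name, "0.1", entries, meta)


# --- the BASIC SEVA collection ---------------------------------------------

# marker_code -> antibiotic; code 5a flags the alternative tetracycline
# module (differs in sequence from the SEVA module of the same slot).
SEVA_MARKERS: dict[str, str] = {
    "1": "ampicillin (AmpR)",
    "2": "kanamycin (KmR)",
    "3": "chloramphenicol (CmR)",
    "4": "streptomycin/spectinomycin (SmR/SpR)",
    "5a": "tetracycline (TcR, alternative module)",
    "6": "gentamicin (GmR)",
}

# ori_code -> replicon; 7ts is the temperature-sensitive pKD46 replicon
# (not in the SEVA database), 5a the RSF1010 homologue.
SEVA_ORIS: dict[str, str] = {
    "5a": "RSF1010 (broad host range)",
    "6": "p15A (low copy)",
    "7": "pSC101 (low copy)",
    "7ts": "pKD46 (pSC101-derived, temperature sensitive)",
    "9": "pBR322 (medium copy)",
}

_MARKER_CODES_BY_LENGTH = sorted(SEVA_MARKERS, key=len, reverse=True)
_SEVA_NAME_RE = re.compile(
    r"^BASIC_SEVA_(?P<body>[0-9a-z]+)\.(?P<version>\d+)$")


@dataclasses.dataclass(frozen=True)
class SevaName:
    """BASIC SEVA nomenclature: marker code + ori code + version,
    rendered ``BASIC_SEVA_<marker><ori>.<version>`` (e.g. BASIC_SEVA_39.10)."""

    marker_code: str
    ori_code: str
    version: int

    def __post_init__(self) -> None:
        if self.marker_code not in SEVA_MARKERS:
            raise ParameterError(f"unknown marker code {self.marker_code!r}")
        if self.ori_code not in SEVA_ORIS:
            raise ParameterError(f"unknown ori code {self.ori_code!r}")
        if self.version < 0:
            raise ParameterError("version must be non-negative")

    def render(self) -> str:
        return f"BASIC_SEVA_{self.marker_code}{self.ori_code}.{self.version}"

    @classmethod
    def parse(cls, text: str) -> "SevaName":
        m = _SEVA_NAME_RE.match(text)
        if not m:
            raise ParameterError(f"not a BASIC SEVA name: {text!r}")
        body = m.group("body")
        for marker in _MARKER_CODES_BY_LENGTH:
            if body.startswith(marker) and body[len(marker):] in SEVA_ORIS:
                return cls(marker, body[len(marker):], int(m.group("version")))
        raise ParameterError(f"unparsable marker/ori codes in {text!r}")


_SEVA_FIXTURE = "BASIC_SEVA_FIXTURES"
SEVA_VERSION = 10


def seva_marker_parts() -> list[tuple[str, BasicPart]]:
    """The packaged six T0 + marker parts, keyed by marker code."""
    out = []
    for code, desc in SEVA_MARKERS.items():
        pid = f"SEVA_T0_MARKER_{code}"
        out.append((code, synthetic_part(
            1100, _entry_seed(_SEVA_FIXTURE, pid), id=pid,
            description=f"T0 terminator + {desc} resistance marker, "
                        "synthetic placeholder")))
    return out


def seva_ori_parts() -> list[tuple[str, BasicPart]]:
    """The packaged five ori + T1 parts, keyed by ori code."""
    out = []
    for code, desc in SEVA_ORIS.items():
        pid = f"SEVA_ORI_{code}_T1"
        out.append((code, synthetic_part(
            900, _entry_seed(_SEVA_FIXTURE, pid), id=pid,
            description=f"{desc} origin of replication + T1 terminator, "
                        "synthetic placeholder")))
    return out


def seva_cassette() -> BasicPart:
    """The mScarlet counter-selection cassette (promoter + RBS + CDS); it is
    LMP/LMS-flanked in every vector and drops out during downstream
    assembly, so background colonies lack the pink phenotype."""
    pid = "MSCARLET_COUNTERSELECTION"
    return synthetic_part(1000, _entry_seed(_SEVA_FIXTURE, pid), id=pid,
                          description="mScarlet counter-selection cassette, "
                                      "synthetic placeholder")


def seva_linkers() -> tuple[BasicLinker, BasicLinker, BasicLinker]:
    """(LMP, LMS, BSEVA_L1) used by the SEVA designer; LMP/LMS come from the
    commercial linker set, BSEVA_L1 is the bespoke neutral joining linker."""
    biolegio = get_collection("BASIC_BIOLEGIO_LINKERS")
    lmp = biolegio["LMP"]
    lms = biolegio["LMS"]
    bseva_l1 = _synthetic_linker(_SEVA_FIXTURE, "BSEVA_L1", role="neutral")
    assert isinstance(lmp, BasicLinker) and isinstance(lms, BasicLinker)
    return lmp, lms, bseva_l1


def design_seva_collection(
        markers: Sequence[tuple[str, BasicPart]] | None = None,
        oris: Sequence[tuple[str, BasicPart]] | None = None,
        cassette: BasicPart | None = None,
        linkers: tuple[BasicLinker, BasicLinker, BasicLinker] | None = None,
        version: int = SEVA_VERSION) -> list[tuple[SevaName, BasicAssembly]]:
    """Combinatorial SEVA vector designer: one assembly per marker x ori.

    Each assembly's element cycle is [LMP, cassette, LMS, marker part,
    BSEVA_L1, ori part]: the counter-selection cassette is LMP/LMS-flanked
    (so it drops out downstream) and marker and ori are joined by the
    neutral BSEVA_L1 linker.  Every design is validated before it is
    returned.
    """
    markers = list(markers) if markers is not None else seva_marker_parts()
    oris = list(oris) if oris is not None else seva_ori_parts()
    cassette = cassette if cassette is not None else seva_cassette()
    lmp, lms, bseva_l1 = linkers if linkers is not None else seva_linkers()
    for codes, what in ((tuple(c for c, _ in markers), "marker"),
                        (tuple(c for c, _ in oris), "ori")):
        if len(set(codes)) != len(codes):
            raise ParameterError(f"duplicate {what} codes: {codes}")
    designs: list[tuple[SevaName, BasicAssembly]] = []
    for m_code, m_part in markers:
        for o_code, o_part in oris:
            name = SevaName(m_code, o_code, version)
            assembly = BasicAssembly(
                id=name.render(),
                elements=(lmp, cassette, lms, m_part, bseva_l1, o_part))
            raise_on_errors(assembly)
            designs.append((name, assembly))
    return designs


def _seva_parts() -> PartLinkerCollection:
    """The 30 shipped BASIC SEVA vectors as storage-format parts.

    Each entry's core is the backbone span that survives cassette drop-out
    (marker + BSEVA_L1 + ori); it is the reusable unit in downstream
    assemblies and is guaranteed BsaI-free.
    """
    name = "BASIC_SEVA_PARTS"
    _, _, bseva_l1 = seva_linkers()
    markers = dict(seva_marker_parts())
    oris = dict(seva_ori_parts())
    entries: dict[str, Entry] = {}
    meta: dict[str, dict[str, str]] = {}
    for m_code, m_part in markers.items():
        for o_code, o_part in oris.items():
            sn = SevaName(m_code, o_code, SEVA_VERSION)
            core = m_part.core + bseva_l1.sequence.bases + o_part.core
            if find_bsai_sites(core):
                raise BasicDnaError(f"{sn.render()}: backbone not BsaI-free")
            entries[sn.render()] = make_part(
                NucleotideSequence(core), sn.render(),
                description=f"BASIC SEVA vector backbone: "
                            f"{SEVA_MARKERS[m_code]} marker + "
                            f"{SEVA_ORIS[o_code]} ori, synthetic placeholder")
            meta[sn.render()] = {"category": "seva_vector",
                                 "marker": m_code, "ori": o_code}
    return PartLinkerCollection(name, str(SEVA_VERSION), entries, meta)


# --- registry ---------------------------------------------------------------

_BUILDERS = {
    ("BASIC_BIOLEGIO_LINKERS", "0.1"): _biolegio_linkers,
    ("BASIC_PROMOTER_PARTS", "0.1"): _promoter_parts,
    ("BASIC_CDS_PARTS", "0.1"): _cds_parts,
    ("BASIC_SEVA_PARTS", str(SEVA_VERSION)): _seva_parts,
}
_DEFAULT_VERSIONS = {
    "BASIC_BIOLEGIO_LINKERS": "0.1",
    "BASIC_PROMOTER_PARTS": "0.1",
    "BASIC_CDS_PARTS": "0.1",
    "BASIC_SEVA_PARTS": str(SEVA_VERSION),
}
_CACHE: dict[tuple[str, str], PartLinkerCollection] = {}


def collection_names() -> list[str]:
    return sorted(_DEFAULT_VERSIONS)


def collection_versions(name: str) -> list[str]:
    if name not in _DEFAULT_VERSIONS:
        raise UnknownCollectionError(
            f"unknown collection {name!r}; available: {collection_names()}")
    return sorted(v for (n, v) in _BUILDERS if n == name)


def get_collection(name: str, version: str | None = None) -> PartLinkerCollection:
    """Fetch a registered collection (documented default version if
    unspecified)."""
    if name not in _DEFAULT_VERSIONS:
        raise UnknownCollectionError(
            f"unknown collection {name!r}; available: {collection_names()}")
    version = version or _DEFAULT_VERSIONS[name]
    key = (name, version)
    if key not in _BUILDERS:
        raise UnknownCollectionError(
            f"unknown version {version!r} of {name}; available: "
            f"{collection_versions(name)}")
    if key not in _CACHE:
        _CACHE[key] = _BUILDERS[key]()
    return _CACHE[key]


def register_collection(collection: PartLinkerCollection,
                        default: bool = False) -> None:
    """Register a user collection (e.g. real catalogue sequences) as a new
    name or version; the drop-in mechanism for substituting placeholders."""
    key = (collection.name, collection.version)
    _BUILDERS[key] = lambda: collection
    _CACHE[key] = collection
    if default or collection.name not in _DEFAULT_VERSIONS:
        _DEFAULT_VERSIONS[collection.name] = collection.version
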