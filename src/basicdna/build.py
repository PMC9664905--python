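"""Build planning: from validated assemblies to a deduplicated clip plan.

A *clip reaction* — one part ligated to the halves of its neighbouring
linkers — is the physical unit of a BASIC build.  Because a purified clip
supports 15-30 downstream assemblies, clips shared between assemblies are
made once; the build plan therefore consists of the unique parts, unique
linkers, deduplicated clips with their assembly associations, and per-part
mass arithmetic targeting 2.5 nM of part in a 30 ul clip reaction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from typing import Mapping, Sequence

from . import config
from .core import BasicAssembly, BasicLinker, BasicPart
from .errors import BuildConsistencyError, ParameterError
from .validate import errors_only, check_assembly


def ds_molecular_weight(bases: str) -> float:
    """Average molecular weight (g/mol) of the double-stranded form.

    Each strand weighs the sum of its 5'-monophosphate residue masses minus
    one water per phosphodiester bond; both strands are summed (a duplex of
    n bp therefore counts n residues of each complementary pair).
    """
    if not bases:
        raise ParameterError("empty sequence")
    masses = config.DNA_RESIDUE_MASS
    comp = config.DNA_COMPLEMENT
    top = sum(masses[b] for b in bases)
    bottom = sum(masses[comp[b]] for b in bases)
    bond_loss = (len(bases) - 1) * config.WATER_MASS
    return top + bottom - 2 * bond_loss


def part_mass(bases: str,
              reaction_volume_l: float = config.DEFAULT_CLIP_REACTION_VOLUME_L,
              final_conc_m: float = config.DEFAULT_PART_CONCENTRATION_M) -> float:
    """Mass (ng) of storage-format part giving ``final_conc_m`` in the clip
    reaction: conc x volume x MW_ds x 1e9."""
    if reaction_volume_l <= 0 or final_conc_m <= 0:
        raise ParameterError("volume and concentration must be positive")
    return final_conc_m * reaction_volume_l * ds_molecular_weight(bases) * 1e9


def clip_multiplicity(total_assemblies: int,
                      capacity: int = config.DEFAULT_CLIP_CAPACITY) -> int:
    """Physical replicates of a clip needed to serve ``total_assemblies``
    when one purified clip supports ``capacity`` assemblies."""
    if total_assemblies < 1 or capacity < 1:
        raise ParameterError("total_assemblies and capacity must be >= 1")
    return math.ceil(total_assemblies / capacity)


@dataclasses.dataclass(frozen=True)
class ClipReaction:
    """One deduplicated clip: part key between prefix/suffix linker keys,
    with the assemblies that require it."""

    prefix_linker: str
    part: str
    suffix_linker: str
    assembly_keys: tuple[str, ...]
    part_mass_ng: float

    @property
    def total_assemblies(self) -> int:
        return len(self.assembly_keys)


@dataclasses.dataclass(frozen=True)
class AssemblyEntry:
    """One assembly of the build: content-hash key, design name, ordered
    clip keys."""

    key: str
    name: str
    clip_keys: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class BasicBuild:
    """The full build plan; serializable via :mod:`basicdna.buildjson`."""

    unique_parts: Mapping[str, BasicPart]
    unique_linkers: Mapping[str, BasicLinker]
    clips_data: Mapping[str, ClipReaction]
    assembly_data: tuple[AssemblyEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "unique_parts", dict(self.unique_parts))
        object.__setattr__(self, "unique_linkers", dict(self.unique_linkers))
        object.__setattr__(self, "clips_data", dict(self.clips_data))
        object.__setattr__(self, "assembly_data", tuple(self.assembly_data))
        self._check_consistency()

    def _check_consistency(self) -> None:
        for ck, clip in self.clips_data.items():
            for ref, pool, what in ((clip.part, self.unique_parts, "part"),
                                    (clip.prefix_linker, self.unique_linkers,
                                     "prefix linker"),
                                    (clip.suffix_linker, self.unique_linkers,
                                     "suffix linker")):
                if ref not in pool:
                    raise BuildConsistencyError(
                        f"clip {ck}: dangling {what} key {ref!r}")
        usage: dict[str, list[str]] = {k: [] for k in self.clips_data}
        for entry in self.assembly_data:
            for ck in entry.clip_keys:
                if ck not in self.clips_data:
                    raise BuildConsistencyError(
                        f"assembly {entry.key}: dangling clip key {ck!r}")
                usage[ck].append(entry.key)
        for ck, clip in self.clips_data.items():
            if tuple(usage[ck]) != clip.assembly_keys:
                raise BuildConsistencyError(
                    f"clip {ck}: assembly_keys {clip.assembly_keys} do not "
                    f"match referencing assemblies {tuple(usage[ck])}")


def assembly_uid(a: BasicAssembly) -> str:
    """Deterministic content hash of an assembly (name + element cycle)."""
    h = hashlib.sha1()
    h.update(a.id.encode())
    for e in a.elements:
        h.update(b"\x00" + e.id.encode() + b"\x01" + e.sequence.bases.encode())
    return h.hexdigest()[:12]


def _register(pool: dict[tuple[str, str], str], by_id: dict[str, str],
              obj: BasicPart | BasicLinker, prefix: str, what: str) -> str:
    ident = (obj.id, obj.sequence.bases)
    key = pool.get(ident)
    if key is not None:
        return key
    if obj.id in by_id:
        raise BuildConsistencyError(
            f"two distinct {what} sequences share id {obj.id!r}; "
            "same-id/different-sequence collisions are not allowed")
    key = f"{prefix}{len(pool)}"
    pool[ident] = key
    by_id[obj.id] = key
    return key


def compute_build(assemblies: Sequence[BasicAssembly],
                  reaction_volume_l: float = config.DEFAULT_CLIP_REACTION_VOLUME_L,
                  final_conc_m: float = config.DEFAULT_PART_CONCENTRATION_M,
                  min_length: int = config.MIN_PART_LENGTH,
                  max_elements: int = config.MAX_ASSEMBLY_ELEMENTS) -> BasicBuild:
    """Compile assemblies into a build plan.

    Clips are deduplicated by the (prefix linker, part, suffix linker)
    identity triple, where identity is (id, bases); keys are assigned in
    first-encounter order (UP0..., UL0..., C0...), so identical input order
    yields byte-identical plans.
    """
    names = [a.id for a in assemblies]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise BuildConsistencyError(f"duplicate assembly ids: {dupes}")
    failing = {a.id: errs for a in assemblies
               if (errs := errors_only(check_assembly(
                   a, max_elements=max_elements, min_length=min_length)))}
    if failing:
        detail = "; ".join(f"{aid}: {[i.code for i in errs]}"
                           for aid, errs in failing.items())
        raise BuildConsistencyError(f"assemblies failed validation: {detail}")

    part_pool: dict[tuple[str, str], str] = {}
    linker_pool: dict[tuple[str, str], str] = {}
    part_by_id: dict[str, str] = {}
    linker_by_id: dict[str, str] = {}
    parts: dict[str, BasicPart] = {}
    linkers: dict[str, BasicLinker] = {}
    clips: dict[tuple[str, str, str], str] = {}
    clip_objs: dict[str, dict] = {}
    entries: list[AssemblyEntry] = []

    for a in assemblies:
        uid = assembly_uid(a)
        clip_keys: list[str] = []
        n = len(a.elements)
        for i, e in enumerate(a.elements):
            if not isinstance(e, BasicPart):
                continue
            prefix = a.elements[(i - 1) % n]
            suffix = a.elements[(i + 1) % n]
            pk = _register(part_pool, part_by_id, e, "UP", "part")
            parts.setdefault(pk, e)
            lk_pre = _register(linker_pool, linker_by_id, prefix, "UL", "linker")
            linkers.setdefault(lk_pre, prefix)
            lk_suf = _register(linker_pool, linker_by_id, suffix, "UL", "linker")
            linkers.setdefault(lk_suf, suffix)
            triple = (lk_pre, pk, lk_suf)
            ck = clips.get(triple)
            if ck is None:
                ck = f"C{len(clips)}"
                clips[triple] = ck
                clip_objs[ck] = {"prefix": lk_pre, "part": pk,
                                 "suffix": lk_suf, "assemblies": []}
            clip_objs[ck]["assemblies"].append(uid)
            clip_keys.append(ck)
        entries.append(AssemblyEntry(key=uid, name=a.id,
                                     clip_keys=tuple(clip_keys)))

    clips_data = {
        ck: ClipReaction(
            prefix_linker=info["prefix"], part=info["part"],
            suffix_linker=info["suffix"],
            assembly_keys=tuple(info["assemblies"]),
            part_mass_ng=part_mass(parts[info["part"]].sequence.bases,
                                   reaction_volume_l, final_conc_m))
        for ck, info in clip_objs.items()
    }
    return BasicBuild(unique_parts=parts, unique_linkers=linkers,
                      clips_data=clips_data, assembly_data=tuple(entries))


def assemblies_from_build(b: BasicBuild) -> list[BasicAssembly]:
    """Re-expand a build into assemblies (used after JSON decode).

    Each assembly's element cycle is reconstructed from its ordered clips as
    [prefix linker, part] pairs; consecutive clips must agree on the shared
    linker, which the build consistency check guarantees for plans produced
    by :func:`compute_build`.
    """
    out: list[BasicAssembly] = []
    for entry in b.assembly_data:
        elements: list = []
        for ck in entry.clip_keys:
            clip = b.clips_data[ck]
            elements.append(b.unique_linkers[clip.prefix_linker])
            elements.append(b.unique_parts[clip.part])
        out.append(BasicAssembly(id=entry.name, elements=tuple(elements)))
    return out


def builds_equal(a: BasicBuild, b: BasicBuild, mass_decimals: int = 2) -> bool:
    """Semantic equality of two builds, comparing masses at the precision
    the JSON codec emits."""
    def norm(build: BasicBuild):
        return (
            {k: (p.id, p.sequence.bases) for k, p in build.unique_parts.items()},
            {k: (l.id, l.sequence.bases) for k, l in build.unique_linkers.items()},
            {k: (c.prefix_linker, c.part, c.suffix_linker, c.assembly_keys,
                 round(c.part_mass_ng, mass_decimals))
             for k, c in build.clips_data.items()},
            tuple((e.key, e.name, e.clip_keys) for e in build.assembly_data),
        )
    return norm(a) == norm(b)
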