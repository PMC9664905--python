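"""BasicBuild Open Standard v0.1: the JSON interchange codec.

A build document carries four top-level collections — ``unique_parts``,
``unique_linkers``, ``clips_data`` and ``assembly_data`` — and is
self-contained: part and linker entries embed their full sequences, so a
design serialized at one site can be decoded and compiled into build
instructions at another with no external resolver.

The human-readable attribute names of the standard, including "assembly
keys", "total assemblies", "clips reactions" and "part mass for 30 μl clip
reaction (ng)", are preserved verbatim as JSON keys; everything else is
normalized snake_case.  Output is canonical: fixed key order, UTF-8,
masses at two decimals, so encode(decode(doc)) is the byte identity.
"""

from __future__ import annotations

import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import config
from .build import AssemblyEntry, BasicBuild, ClipReaction
from .core import BasicLinker, BasicPart, LinkerHalf, NucleotideSequence, SequenceFeature
from .errors import DanglingKeyError, SchemaError, VersionMismatchError

MASS_KEY = "part mass for 30 μl clip reaction (ng)"
MASS_DECIMALS = 2


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class FeatureModel(_Strict):
    label: str
    kind: str
    start: int = Field(ge=0)
    end: int = Field(gt=0)
    strand: Literal[1, -1] = 1


class PartModel(_Strict):
    id: str
    sequence: str = Field(min_length=1)
    description: str = ""
    features: list[FeatureModel] = Field(default_factory=list)


class HalfModel(_Strict):
    half_id: str
    sequence: str = Field(min_length=1)


class LinkerModel(_Strict):
    id: str
    sequence: str = Field(min_length=1)
    role: Literal["boundary_LMP", "boundary_LMS", "neutral", "functional"]
    methylated: bool = False
    prefix_half: HalfModel
    suffix_half: HalfModel


class ClipModel(_Strict):
    prefix_linker_key: str
    part_key: str
    suffix_linker_key: str
    assembly_keys: list[str] = Field(alias="assembly keys", min_length=1)
    total_assemblies: int = Field(alias="total assemblies", ge=1)
    part_mass_ng: float = Field(alias=MASS_KEY, gt=0)


class AssemblyModel(_Strict):
    key: str
    name: str
    clip_keys: list[str] = Field(alias="clips reactions", min_length=1)


class BuildDocument(_Strict):
    """Pydantic mirror of the BasicBuild Open Standard v0.1."""

    schema_version: str
    unique_parts: dict[str, PartModel]
    unique_linkers: dict[str, LinkerModel]
    clips_data: dict[str, ClipModel]
    assembly_data: list[AssemblyModel]


def build_schema() -> dict:
    """The shipped JSON Schema of the standard (draft 2020-12)."""
    schema = BuildDocument.model_json_schema(by_alias=True)
    schema["$id"] = "basicbuild-standard-0.1"
    return schema


def _document_dict(b: BasicBuild) -> dict:
    doc: dict = {"schema_version": config.BUILD_SCHEMA_VERSION}
    doc["unique_parts"] = {
        k: {"id": p.id, "sequence": p.sequence.bases,
            "description": p.description,
            "features": [{"label": f.label, "kind": f.kind, "start": f.start,
                          "end": f.end, "strand": f.strand}
                         for f in p.features]}
        for k, p in b.unique_parts.items()}
    doc["unique_linkers"] = {
        k: {"id": l.id, "sequence": l.sequence.bases, "role": l.role,
            "methylated": l.methylated,
            "prefix_half": {"half_id": l.prefix_half.half_id,
                            "sequence": l.prefix_half.sequence.bases},
            "suffix_half": {"half_id": l.suffix_half.half_id,
                            "sequence": l.suffix_half.sequence.bases}}
        for k, l in b.unique_linkers.items()}
    doc["clips_data"] = {
        k: {"prefix_linker_key": c.prefix_linker, "part_key": c.part,
            "suffix_linker_key": c.suffix_linker,
            "assembly keys": list(c.assembly_keys),
            "total assemblies": c.total_assemblies,
            MASS_KEY: round(c.part_mass_ng, MASS_DECIMALS)}
        for k, c in b.clips_data.items()}
    doc["assembly_data"] = [
        {"key": e.key, "name": e.name, "clips reactions": list(e.clip_keys)}
        for e in b.assembly_data]
    return doc


def encode_build(b: BasicBuild) -> str:
    """Serialize a build plan as a canonical BasicBuild document."""
    return json.dumps(_document_dict(b), indent=2, ensure_ascii=False) + "\n"


def _check_references(doc: BuildDocument) -> None:
    for ck, clip in doc.clips_data.items():
        if clip.part_key not in doc.unique_parts:
            raise DanglingKeyError(
                f"clips_data/{ck}: unknown part key {clip.part_key!r}")
        for lk in (clip.prefix_linker_key, clip.suffix_linker_key):
            if lk not in doc.unique_linkers:
                raise DanglingKeyError(
                    f"clips_data/{ck}: unknown linker key {lk!r}")
        if clip.total_assemblies != len(clip.assembly_keys):
            raise SchemaError(
                f"clips_data/{ck}: 'total assemblies' "
                f"{clip.total_assemblies} != len('assembly keys') "
                f"{len(clip.assembly_keys)}")
    assembly_keys = {a.key for a in doc.assembly_data}
    for ck, clip in doc.clips_data.items():
        for ak in clip.assembly_keys:
            if ak not in assembly_keys:
                raise DanglingKeyError(
                    f"clips_data/{ck}: unknown assembly key {ak!r}")
    for a in doc.assembly_data:
        for ck in a.clip_keys:
            if ck not in doc.clips_data:
                raise DanglingKeyError(
                    f"assembly_data/{a.key}: unknown clip key {ck!r}")


def decode_build(text: str,
                 ip: str = config.DEFAULT_IP,
                 is_: str = config.DEFAULT_IS) -> BasicBuild:
    """Decode a BasicBuild document into a referentially checked plan.

    Raises :class:`SchemaError` (with the offending JSON path),
    :class:`DanglingKeyError` or :class:`VersionMismatchError`.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if isinstance(raw, dict):
        version = raw.get("schema_version")
        if version != config.BUILD_SCHEMA_VERSION:
            raise VersionMismatchError(
                f"unknown schema_version {version!r}; this codec reads "
                f"{config.BUILD_SCHEMA_VERSION!r}")
    try:
        doc = BuildDocument.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = "/".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: {first['msg']}") from exc
    _check_references(doc)

    parts = {
        k: BasicPart(
            id=m.id, sequence=NucleotideSequence(m.sequence),
            features=tuple(SequenceFeature(f.label, f.kind, f.start, f.end,
                                           f.strand) for f in m.features),
            description=m.description, ip=ip, is_=is_)
        for k, m in doc.unique_parts.items()}
    linkers = {
        k: BasicLinker(
            id=m.id, sequence=NucleotideSequence(m.sequence),
            prefix_half=LinkerHalf(m.prefix_half.half_id,
                                   NucleotideSequence(m.prefix_half.sequence),
                                   "prefix"),
            suffix_half=LinkerHalf(m.suffix_half.half_id,
                                   NucleotideSequence(m.suffix_half.sequence),
                                   "suffix"),
            role=m.role, methylated=m.methylated)
        for k, m in doc.unique_linkers.items()}
    clips = {
        k: ClipReaction(prefix_linker=m.prefix_linker_key, part=m.part_key,
                        suffix_linker=m.suffix_linker_key,
                        assembly_keys=tuple(m.assembly_keys),
                        part_mass_ng=m.part_mass_ng)
        for k, m in doc.clips_data.items()}
    entries = tuple(AssemblyEntry(key=m.key, name=m.name,
                                  clip_keys=tuple(m.clip_keys))
                    for m in doc.assembly_data)
    return BasicBuild(unique_parts=parts, unique_linkers=linkers,
                      clips_data=clips, assembly_data=entries)
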