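"""Design-rule engine: catch designs that would fail at the bench.

Rules implemented (all severity ``error`` except the capacity warning):

* ``SHORT_PART`` — cores shorter than 100 bp are lost during magnetic-bead
  purification of linker-ligated parts.
* ``INTERNAL_BSAI`` — a BsaI recognition site (GGTCTC / bottom-strand
  GAGACC) inside the part core would be cut during the clip reaction;
  sites resident in the iP/iS flanks are the intended ones and exempt.
* ``NOT_ALTERNATING`` / ``UNBALANCED`` — parts and linkers must alternate
  around the circle with equal counts, starting with a linker.
* ``DUPLICATE_LINKER`` — a specific linker may be used once per round.
* ``HALF_CLASH`` — two distinct linkers sharing a prefix-half identity (or
  a suffix-half identity) would misanneal during assembly.
* ``CAPACITY_WARNING`` — more than 14 combined elements exceeds the
  demonstrated single-round capacity (warning, not error).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Literal

from . import config
from .core import BasicAssembly, BasicLinker, BasicPart
from .errors import AssemblyValidationError

IssueCode = Literal["SHORT_PART", "INTERNAL_BSAI", "DUPLICATE_LINKER",
                    "HALF_CLASH", "NOT_ALTERNATING", "UNBALANCED",
                    "CAPACITY_WARNING"]


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    code: IssueCode
    severity: Literal["error", "warning"]
    subject: str
    message: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), ensure_ascii=False)


def _issue(code: IssueCode, subject: str, message: str) -> ValidationIssue:
    severity = "warning" if code == "CAPACITY_WARNING" else "error"
    return ValidationIssue(code, severity, subject, message)


def find_bsai_sites(bases: str) -> list[tuple[int, int]]:
    """All BsaI recognition-site intervals [start, end) on either strand,
    reported in top-strand coordinates."""
    hits: list[tuple[int, int]] = []
    for motif in (config.BSAI_SITE, config.BSAI_SITE_RC):
        start = bases.find(motif)
        while start != -1:
            hits.append((start, start + len(motif)))
            start = bases.find(motif, start + 1)
    return sorted(set(hits))


def check_part(p: BasicPart,
               min_length: int = config.MIN_PART_LENGTH) -> list[ValidationIssue]:
    """Screen one part: length rule plus the two-strand BsaI scan.

    The scan runs over the full storage sequence so that sites straddling a
    flank/core junction are caught; sites wholly inside the iP or iS flank
    are the intended ones and exempt.
    """
    issues: list[ValidationIssue] = []
    if len(p.core) < min_length:
        issues.append(_issue(
            "SHORT_PART", p.id,
            f"core is {len(p.core)} bp; parts below {min_length} bp are lost "
            "during purification"))
    bases = p.sequence.bases
    ip_end, is_start = len(p.ip), len(bases) - len(p.is_)
    for start, end in find_bsai_sites(bases):
        in_ip = end <= ip_end
        in_is = start >= is_start
        if not (in_ip or in_is):
            issues.append(_issue(
                "INTERNAL_BSAI", p.id,
                f"BsaI site at [{start}, {end}) outside the iP/iS flanks"))
    return issues


def check_assembly(a: BasicAssembly,
                   max_elements: int = config.MAX_ASSEMBLY_ELEMENTS,
                   min_length: int = config.MIN_PART_LENGTH) -> list[ValidationIssue]:
    """Run every structural rule plus per-part screens; returns issues as data."""
    issues: list[ValidationIssue] = []
    elems = a.elements

    if elems and not isinstance(elems[0], BasicLinker):
        issues.append(_issue("NOT_ALTERNATING", a.id,
                             "assembly must begin with a linker"))
    for i in range(len(elems)):
        here, there = elems[i], elems[(i + 1) % len(elems)]
        if isinstance(here, BasicLinker) == isinstance(there, BasicLinker):
            kind = "linkers" if isinstance(here, BasicLinker) else "parts"
            issues.append(_issue(
                "NOT_ALTERNATING", a.id,
                f"adjacent {kind} at cyclic positions {i} and "
                f"{(i + 1) % len(elems)}"))
            break  # one alternation report is enough

    linkers, parts = a.linkers, a.parts
    if len(linkers) != len(parts):
        issues.append(_issue(
            "UNBALANCED", a.id,
            f"{len(linkers)} linkers vs {len(parts)} parts"))

    seen: set[str] = set()
    for l in linkers:
        if l.id in seen:
            issues.append(_issue("DUPLICATE_LINKER", a.id,
                                 f"linker {l.id!r} used more than once"))
        seen.add(l.id)

    distinct = {l.id: l for l in linkers}.values()
    for side in ("prefix", "suffix"):
        by_identity: dict[str, BasicLinker] = {}
        for l in distinct:
            half = l.prefix_half if side == "prefix" else l.suffix_half
            other = by_identity.get(half.identity)
            if other is not None and other.id != l.id:
                issues.append(_issue(
                    "HALF_CLASH", a.id,
                    f"linkers {other.id!r} and {l.id!r} share {side}-half "
                    f"identity {half.identity!r}"))
            else:
                by_identity[half.identity] = l

    if len(elems) > max_elements:
        issues.append(_issue(
            "CAPACITY_WARNING", a.id,
            f"{len(elems)} elements exceed the demonstrated per-round "
            f"capacity of {max_elements}"))

    for p in {p.id: p for p in parts}.values():
        issues.extend(check_part(p, min_length=min_length))
    return issues


def errors_only(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in issues if i.severity == "error"]


def raise_on_errors(a: BasicAssembly,
                    max_elements: int = config.MAX_ASSEMBLY_ELEMENTS,
                    min_length: int = config.MIN_PART_LENGTH) -> list[ValidationIssue]:
    """Eager gate used by the high-level interface: raise on error-severity
    issues, return (warning-only) issues otherwise."""
    issues = check_assembly(a, max_elements=max_elements, min_length=min_length)
    errs = errors_only(issues)
    if errs:
        raise AssemblyValidationError(errs)
    return issues


def issues_to_jsonl(issues: Iterable[ValidationIssue]) -> str:
    """Machine-readable report: one JSON object per line."""
    return "".join(i.to_json() + "\n" for i in issues)
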