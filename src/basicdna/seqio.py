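"""Sequence I/O and oligo design.

Reading/writing goes through Biopython's :mod:`Bio.SeqIO` (GenBank and
FASTA dialects), mapped onto the package's value types with coordinates
0-based half-open internally and GenBank's 1-based inclusive convention on
disk.  The design helpers cover the two wet-lab entry points of the BASIC
workflow: overhang-PCR primers that add the iP/iS flanks to an existing
sequence, and the four oligonucleotides (long + adapter per half) that
physically realize a linker.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp

from . import config
from .core import (BasicAssembly, BasicLinker, BasicPart, NucleotideSequence,
                   SequenceFeature, assembled_sequence, reverse_complement)
from .errors import (EmptyFileError, FormatCapabilityError, ParameterError,
                     ParseError, PrimerDesignError)

# Fixed date stamp so GenBank output is byte-for-byte deterministic.
_GENBANK_DATE = "01-JAN-1980"

_LABEL_QUALIFIERS = ("label", "gene", "product", "note", "standard_name")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """Format-neutral record: what read_records yields and write_records takes."""

    id: str
    sequence: NucleotideSequence
    features: tuple[SequenceFeature, ...] = ()
    description: str = ""


def part_to_record(p: BasicPart) -> SequenceRecord:
    return SequenceRecord(p.id, p.sequence, p.features, p.description)


def assembly_to_record(a: BasicAssembly, annotate_linkers: bool = True) -> SequenceRecord:
    """Assembled circular record; optionally one misc_feature per linker."""
    seq, features = assembled_sequence(a)
    feats = list(features)
    if annotate_linkers:
        offset = 0
        for e in a.elements:
            length = len(e.sequence.bases) if isinstance(e, BasicLinker) else len(e.core)
            if isinstance(e, BasicLinker):
                feats.append(SequenceFeature(e.id, "misc_feature",
                                             offset, offset + length))
            offset += length
        feats.sort(key=lambda f: (f.start, f.end))
    return SequenceRecord(a.id, seq, tuple(feats),
                          description="BASIC assembly")


def _feature_label(f: SeqFeature) -> str:
    for q in _LABEL_QUALIFIERS:
        if q in f.qualifiers and f.qualifiers[q]:
            return str(f.qualifiers[q][0])
    return f.type


def read_records(source: Union[str, TextIO], format: str) -> list[SequenceRecord]:
    """Parse a GenBank or FASTA stream (or path) into records.

    GenBank features become :class:`SequenceFeature` values (coordinates are
    already 0-based half-open inside Biopython); FASTA records carry no
    features.  Topology is taken from the GenBank LOCUS line when present.
    """
    if format not in ("genbank", "fasta"):
        raise ParameterError(f"unsupported format {format!r}")
    handle = open(source) if isinstance(source, str) else source
    try:
        try:
            seq_records = list(SeqIO.parse(handle, format))
        except Exception as exc:  # Biopython raises assorted ValueError types
            raise ParseError(f"could not parse {format} input: {exc}") from exc
    finally:
        if isinstance(source, str):
            handle.close()
    if not seq_records:
        raise EmptyFileError(f"no {format} records found")
    out: list[SequenceRecord] = []
    for rec in seq_records:
        circular = rec.annotations.get("topology", "linear") == "circular"
        features = []
        for f in rec.features:
            if f.location is None:
                continue
            features.append(SequenceFeature(
                label=_feature_label(f), kind=f.type,
                start=int(f.location.start), end=int(f.location.end),
                strand=-1 if f.location.strand == -1 else 1))
        out.append(SequenceRecord(
            id=rec.id, sequence=NucleotideSequence(str(rec.seq), circular),
            features=tuple(features), description=rec.description))
    return out


def _to_seqrecord(r: SequenceRecord) -> SeqRecord:
    rec = SeqRecord(Seq(r.sequence.bases), id=r.id, name=r.id[:16],
                    description=r.description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if r.sequence.circular else "linear"
    rec.annotations["date"] = _GENBANK_DATE
    for f in r.features:
        rec.features.append(SeqFeature(
            FeatureLocation(f.start, f.end, strand=f.strand), type=f.kind,
            qualifiers={"label": [f.label]}))
    return rec


def write_records(records: Iterable[SequenceRecord], format: str,
                  stream: TextIO) -> None:
    """Write records as GenBank or FASTA; deterministic byte-for-byte.

    Circular topology is only representable in GenBank; writing a circular
    record to FASTA raises :class:`FormatCapabilityError`.
    """
    if format not in ("genbank", "fasta"):
        raise ParameterError(f"unsupported format {format!r}")
    records = list(records)
    if format == "fasta":
        for r in records:
            if r.sequence.circular:
                raise FormatCapabilityError(
                    f"record {r.id!r} is circular; FASTA cannot represent "
                    "topology — use GenBank")
    SeqIO.write([_to_seqrecord(r) for r in records], stream, format)


def records_to_text(records: Iterable[SequenceRecord], format: str) -> str:
    buf = io.StringIO()
    write_records(records, format, buf)
    return buf.getvalue()


# --- primer design ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PrimerPair:
    """Overhang-PCR primers adding iP (forward tail) and iS (reverse tail,
    as its reverse complement) to a template; Tm refers to the annealing
    region only."""

    forward: str
    reverse: str
    forward_tm: float
    reverse_tm: float
    forward_anneal: str
    reverse_anneal: str


def annealing_tm(bases: str) -> float:
    """Nearest-neighbour melting temperature under the package's documented
    conditions (see :data:`basicdna.config.TM_CONDITIONS`)."""
    return float(MeltingTemp.Tm_NN(Seq(bases), **config.TM_CONDITIONS))


def _pick_anneal(candidates: list[str], target_tm: float,
                 tm_window: float, end: str) -> tuple[str, float]:
    best: tuple[float, int, str, float] | None = None
    for cand in candidates:
        tm = annealing_tm(cand)
        if abs(tm - target_tm) > tm_window:
            continue
        key = (abs(tm - target_tm), -len(cand))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cand, tm)
    if best is None:
        raise PrimerDesignError(
            f"no {end} annealing region of {config.PRIMER_MIN_ANNEAL}-"
            f"{config.PRIMER_MAX_ANNEAL} nt has Tm within "
            f"{target_tm} +/- {tm_window} C")
    return best[2], best[3]


def design_ip_is_primers(template: NucleotideSequence,
                         target_tm: float = config.DEFAULT_TARGET_TM,
                         tm_window: float = config.DEFAULT_TM_WINDOW,
                         ip: str = config.DEFAULT_IP,
                         is_: str = config.DEFAULT_IS) -> PrimerPair:
    """Design the iP/iS overhang-PCR primer pair for a linear template.

    Annealing regions are terminal substrings (15-36 nt) whose Tm falls in
    the window; among candidates the closest to target wins, longest first
    on ties.  The forward primer is iP + 5' annealing region; the reverse is
    reverse-complement(iS) + reverse-complement of the 3' terminus.
    """
    if template.circular:
        raise ParameterError("template must be linear")
    bases = template.bases
    if len(bases) < 40:
        raise ParameterError(
            f"template of {len(bases)} bp too short for primer design (>= 40)")
    max_len = min(config.PRIMER_MAX_ANNEAL, len(bases))
    lengths = range(config.PRIMER_MIN_ANNEAL, max_len + 1)
    fwd_anneal, fwd_tm = _pick_anneal([bases[:n] for n in lengths],
                                      target_tm, tm_window, "5'")
    rev_candidates = [reverse_complement(bases[-n:]) for n in lengths]
    rev_anneal, rev_tm = _pick_anneal(rev_candidates, target_tm, tm_window, "3'")
    return PrimerPair(
        forward=ip + fwd_anneal,
        reverse=reverse_complement(is_) + rev_anneal,
        forward_tm=fwd_tm, reverse_tm=rev_tm,
        forward_anneal=fwd_anneal, reverse_anneal=rev_anneal)


# --- linker oligos ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LinkerOligoSet:
    """The four oligos realizing a linker: a long oligo per half plus the
    short adapter annealed to it (all written 5'->3')."""

    prefix_long: str
    prefix_adapter: str
    suffix_long: str
    suffix_adapter: str


def linker_oligos(l: BasicLinker,
                  adapter_length: int = config.DEFAULT_ADAPTER_LENGTH) -> LinkerOligoSet:
    """Compute the adapter + long oligonucleotide for each linker half.

    The prefix half is the 5' half of the linker, so its part junction —
    where the upstream part's iS end ligates — is its 5' terminus; the
    suffix half is the 3' half, with its junction at its 3' terminus against
    the downstream part's iP end.  Each adapter reverse-complements the
    ``adapter_length`` junction-adjacent bases of its long oligo, forming
    the short duplex that presents the ligatable overhang.
    """
    prefix_long = l.prefix_half.sequence.bases
    suffix_long = l.suffix_half.sequence.bases
    if adapter_length < 1:
        raise ParameterError("adapter_length must be >= 1")
    if adapter_length > len(prefix_long) or adapter_length > len(suffix_long):
        raise ParameterError(
            f"adapter_length {adapter_length} exceeds a linker half of "
            f"linker {l.id!r}")
    return LinkerOligoSet(
        prefix_long=prefix_long,
        prefix_adapter=reverse_complement(prefix_long[:adapter_length]),
        suffix_long=suffix_long,
        suffix_adapter=reverse_complement(suffix_long[-adapter_length:]),
    )
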