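# Methods

## The assembly model

BASIC composes circular constructs from an alternating cycle of linkers
and parts, beginning with a linker. `basicdna` models the assembled
sequence as the concatenation, in element order, of each linker's full
double-stranded sequence followed by the next part's *core* (the storage
sequence with the iP/iS flanks removed), marked circular. Sub-scar
chemistry — BsaI overhang fill-in and ligation at the linker/part
junctions — is deliberately not modelled: the assembled record is exactly
linker + core concatenation, and scar-level fidelity is delegated to the
linker sequence definitions themselves. This matches the role of the
in-silico export (reference sequences and annotation), not a reaction
simulation.

Coordinates are 0-based half-open internally and converted to GenBank's
1-based inclusive convention on output. Circular sequences compare equal
up to rotation via the lexicographically minimal rotation; the canonical
written rotation starts at element 0's first base. Sequence identity (for
deduplication) is case-insensitive; IUPAC ambiguity codes are rejected
with a distinct error rather than silently normalized, because a
degenerate base in a build plan is a design error, not a spelling one.

**Idempotent conversion.** `assembly_to_part` extracts the span of the
assembled circle from the end of the single `boundary_LMP` linker forward
to the start of the single `boundary_LMS` linker and re-flanks it with
iP/iS. With this convention the fixed-point property holds by
construction: re-assembling the derived part between the same LMP/LMS pair
in the same backbone reproduces the original circle up to rotation. The
boundary linkers themselves are wholly replaced by the fresh iP/iS flanks;
for chemical verisimilitude the shipped LMP placeholder ends with the iP
sequence and the shipped LMS placeholder begins with iS, but no logic
depends on that.

**Linker halves.** A linker's `prefix_half` is its 5′ half and
`suffix_half` its 3′ half as written in the assembly; the prefix half's
part junction is therefore its 5′ terminus (against the upstream part's iS
end) and the suffix half's junction is its 3′ terminus (against the
downstream part's iP end). In a clip reaction the part is flanked by the
*suffix half of its preceding linker* and the *prefix half of its
following linker*; the manual clip table prints exactly those two half
identities. Half identity labels (e.g. a shared UTR) drive the clash rule;
where a label is absent the half's sequence is its identity.

## Validation rules and thresholds

| rule | trigger | severity | default |
|---|---|---|---|
| SHORT_PART | core length < `min_length` | error | 100 bp |
| INTERNAL_BSAI | GGTCTC or GAGACC outside the iP/iS flanks | error | — |
| NOT_ALTERNATING | cyclically adjacent same-kind elements, or a part-first cycle | error | — |
| UNBALANCED | linker count ≠ part count | error | — |
| DUPLICATE_LINKER | a linker id used twice in one round | error | — |
| HALF_CLASH | two distinct linkers sharing a prefix-half (or suffix-half) identity | error | — |
| CAPACITY_WARNING | parts + linkers > `max_elements` | warning | 14 |

"Significantly shorter than 100 bp" is resolved to a hard threshold at
100, applied to the part core (not the flanked storage sequence), because
the loss mechanism — washout of short linker-ligated fragments during
magnetic-bead purification — acts on the ligated core. The BsaI scan runs
over the full storage sequence so that sites straddling a flank/core
junction are caught, exempting only sites wholly inside a flank (the two
intentional ones). The 14-element capacity is a demonstrated achievement,
not a chemical impossibility, hence a warning. Validation is eager in the
high-level interface (`BasicAssembly.checked`, `assembled_sequence`,
`compute_build`) and available as pure functions returning issues-as-data
for batch/CI use.

## Clip arithmetic

Clips are deduplicated by the identity triple (prefix linker, part, suffix
linker), where part and linker identity is the *(id, sequence)* pair: two
different sequences sharing an id are rejected loudly rather than merged,
since that is precisely the mix-up a build plan exists to prevent. Keys
(`UP0…`, `UL0…`, `C0…`) are assigned in first-encounter order and assembly
ids are 12-hex-character content hashes of name + element cycle, so
identical inputs give byte-identical plans.

The part mass for a clip reaction is `m = c · V · M_ds · 10⁹` ng with
defaults c = 2.5 nM and V = 30 µl. `M_ds` is the average duplex molecular
weight: per strand, the sum of 2′-deoxynucleoside-5′-monophosphate residue
masses (A 331.2218, C 307.1971, G 347.2212, T 322.2085 g/mol) minus one
water (18.0153) per phosphodiester bond, both strands summed. The tests
cross-check this against Biopython's atomic-composition computation.
The mass refers to the flanked storage-format part — that is the species
pipetted into the clip reaction; the flanks are only removed by digestion
within it. Physical clip replicates are ⌈total assemblies / capacity⌉
with capacity defaulting to 15, the conservative end of the supported
15–30 range.

## The BasicBuild JSON document

The codec emits a fixed top-level order (`schema_version`, `unique_parts`,
`unique_linkers`, `clips_data`, `assembly_data`), UTF-8, two-decimal
masses, and preserves the standard's human-readable attribute names
verbatim ("assembly keys", "total assemblies", "clips reactions", "part
mass for 30 μl clip reaction (ng)"); all other keys are snake_case. The
schema (pydantic models; JSON Schema via `build_schema()`) forbids unknown
fields, so every emitted field is constrained — verified by mutation
tests. Unknown `schema_version` values are rejected, not coerced.
Documents are self-contained (full sequences embedded); decoding assumes
the package's configured iP/iS flanks unless overridden.

Masses are emitted at two decimals (0.01 ng is far below pipetting
accuracy); in-memory plans keep full precision, and the concentration
inversion property is exact there. `encode(decode(doc))` is the byte
identity on canonical documents.

## Instruction exports

Both exporters derive from the same intermediate tables, so they cannot
diverge. The default recipe is a 5 µl assembly reaction with 1/10 volume
of 10× assembly buffer and 500 nL per purified clip; water tops each well
to the total. Volumes are quantized to the 25 nL droplet quantum of
Echo 525-class instruments; quantization rounds buffer and water only —
never clips, whose stoichiometry is the sensitive quantity — and the
remainder is reconciled into the water transfer, so every destination well
sums exactly to the recipe total. Wells fill column-major from A1 on a
384-well source and a 96-well destination plate, independently; a clip
serving more than `capacity` assemblies occupies one source well per
replicate and assemblies rotate to a fresh replicate every `capacity`
uses. The manual protocol is rendered as deterministic plain text with
four ordered sections (clip reactions, purification, assembly reactions,
transformation) plus CSV twins of the clip and assembly tables.

## Collections and synthetic placeholders

The commercial linker set and the vector/part collections are shipped as
*structured synthetic placeholders*: correct ids, roles, half identities
and cardinalities (65 linkers; 60 promoters; 10 CDS parts; 30 SEVA
vectors — 165 sequences in total), with sequences synthesized
deterministically at import (per-entry seed = CRC32 of `collection:id`).
The real catalogue sequences are proprietary; `register_collection` is the
drop-in mechanism for substituting them, optionally as a new default
version of the same collection name.

The 65-linker set comprises LMP + LMS (methylated boundaries), 18 neutral
and 18 fusion linkers, and 27 UTR/RBS linkers organised as 3 UTR
prefix-half identities × 9 RBS suffix-half identities each; because RBS
suffix identities are not UTR-specific, 3 × 27 = 81 UTR/RBS half
combinations are derivable from the labelled subset
(`utr_rbs_combinations`). How the physical catalogue partitions its 81
combinations over 65 linkers is not public; this encoding reproduces the
counts while keeping the half-recombination rule explicit.

Every synthetic core begins and ends with `A`. Neither BsaI motif contains
`AA`, so no junction of two such sequences (or of a core against the fixed
iP/iS flanks, checked case by case) can create a restriction site that
straddles it — which is what lets composed fixtures (SEVA backbones,
derived parts) pass the BsaI screen by construction. Beyond motif
exclusion and this boundary convention the placeholder sequences are
uniform random DNA: they carry none of the biological signal (promoter
motifs, codon structure, GC skew, repeats) of real parts, so passing tests
demonstrate the correctness of the design logic and arithmetic, not the
behaviour of real sequences in a thermocycler.

**SEVA designer.** `design_seva_collection` crosses the packaged six
markers (codes 1, 2, 3, 4, 5a, 6 — 5a flagging the alternative
tetracycline module) with five oris (5a RSF1010, 6 p15A, 7 pSC101, 7ts the
temperature-sensitive pKD46 replicon, 9 pBR322), producing the element
cycle [LMP, cassette, LMS, marker, BSEVA_L1, ori] and names rendered
`BASIC_SEVA_<marker><ori>.<version>` (shipped version 10; parsing tries
marker codes longest-first, which is unambiguous over these code sets).
The shipped `BASIC_SEVA_PARTS` entries store the *backbone* span — marker
+ BSEVA_L1 + ori, the region that survives drop-out of the LMP/LMS-flanked
mScarlet counter-selection cassette — as the part core, since that is the
reusable unit in downstream assemblies and it keeps every entry BsaI-free
(the boundary linkers, which legitimately carry BsaI sites, are excluded).

## Primer and oligo design

Overhang-PCR primers that add iP/iS to an existing sequence choose
annealing regions from the template termini over lengths 15–36 nt, scored
by a nearest-neighbour melting temperature (Biopython `Tm_NN`; 25 nM each
strand, 50 mM Na⁺, no Mg²⁺ — all in `config.TM_CONDITIONS` and
overridable). Candidates outside the target ± window are discarded; among
the rest the closest Tm wins, longest first on exact ties, making the
output deterministic. Templates under 40 bp are rejected. Linker-half
oligos: the long oligo is the half itself; the adapter is the reverse
complement of the `adapter_length` (default 12 nt) junction-adjacent bases
of the long oligo, per the half-orientation convention above. The adapter
length is a config constant because published linker sets do not state the
physical partition; oligo-level compatibility with a specific commercial
catalogue requires substituting its real sequences.

## Numerical and degenerate-input choices

- Float comparisons in the mass arithmetic are exact inversions by
  construction; tests assert at 1e-12 relative.
- `compute_build([])` is valid and yields an empty, schema-valid document.
- An assembly consisting of a single linker + part pair is valid (the part
  wraps to the same linker on both sides, giving one clip).
- Tie-breaks: primer candidates longest-first on equal Tm distance;
  buffer volume rounds half-away-from-zero to the droplet quantum.
- `synthetic_bases` resamples only the offending window on a motif hit,
  falling back to full regeneration, and fails loudly for pathological
  motif sets rather than looping forever.

## Scope and limitations

Problem sizes throughout (30-vector collection, randomized builds of up to
50 assemblies, 300-sample property scans) are desk-scale design-logic
checks; the suite runs in a few seconds. Not modelled: ligation
thermodynamics and misannealing between halves, methylation beyond a
boolean flag, host-specific plasmid stability, primer specificity against
genomes, SBOL import (the record interface admits it later), and wet-lab
execution itself. The manual protocol text is a workflow skeleton, not a
validated bench protocol.
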