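# basicdna

Design automation for **BASIC DNA assembly** (Biopart Assembly Standard for
Idempotent Cloning). BASIC builds circular constructs from alternating
modular **parts** and **linkers**: parts live in a single storage format —
core sequence flanked by the integrated prefix (iP) and suffix (iS), each
carrying a BsaI site — and linkers, supplied as two oligonucleotide
*halves*, join the excised cores. Because an assembly whose interior is
flanked by the methylated LMP/LMS boundary linkers reconstitutes the
storage format, assemblies are themselves parts: the method is idempotent
and supports hierarchical construction.

`basicdna` is for synthetic biologists and biofoundry engineers planning
BASIC builds programmatically. It provides:

- **Domain model** — `BasicPart`, `BasicLinker`, `BasicAssembly`; assembled
  circular sequences with annotation carry-over; idempotent
  assembly→part conversion (`assembly_to_part`).
- **Validation** — a rule engine catching designs that fail at the bench:
  parts under 100 bp (lost during purification), internal BsaI sites
  (GGTCTC / GAGACC), linker reuse within a round, incompatible linker-half
  identities, non-alternating or unbalanced element cycles, and a warning
  above the demonstrated 14-element-per-round capacity.
- **Build planning** — clip reactions (part + neighbouring linker halves)
  deduplicated across assemblies; the part mass that puts each part at
  2.5 nM in a 30 µl clip reaction, `m = c·V·M_ds(part)·10⁹` ng; physical
  clip multiplicities at ⌈assemblies / capacity⌉ with capacity 15.
- **BasicBuild Open Standard v0.1** — a canonical, self-contained JSON
  interchange format (`unique_parts`, `unique_linkers`, `clips_data`,
  `assembly_data`) with a shipped schema; encode/decode is a byte-level
  round trip.
- **Instruction exporters** — acoustic-liquid-handler picklists (clips +
  water/buffer CSVs, 25 nL droplet quantum, per-well volume conservation)
  and a plain-text manual protocol with CSV table twins.
- **Collections** — versioned part/linker registries mirroring the BASIC
  ecosystem (65-linker commercial set with 81 derivable UTR/RBS half
  combinations, 60 promoters, CDS parts, the 30-vector BASIC SEVA
  collection) as structured synthetic placeholders, plus the combinatorial
  SEVA designer and nomenclature (`BASIC_SEVA_<marker><ori>.<version>`).
- **Sequence I/O** — GenBank/FASTA read/write with feature preservation,
  iP/iS overhang-PCR primer design (nearest-neighbour Tm), and the four
  oligos (long + adapter per half) realizing a custom linker.

## Worked example

```python
import basicdna as bd

# design the 30-vector SEVA-style collection: 6 markers x 5 oris, the
# mScarlet counter-selection cassette flanked by LMP/LMS, marker and ori
# joined by the neutral BSEVA_L1 linker
designs = bd.design_seva_collection()
print(len(designs), designs[10][0].render())

# compile into a deduplicated build plan and serialize it
plan = bd.compute_build([assembly for _, assembly in designs])
print(len(plan.clips_data), "unique clips for", len(plan.assembly_data), "assemblies")

clip = next(iter(plan.clips_data.values()))
print(clip.total_assemblies, round(clip.part_mass_ng, 2))
```

prints

```
30 BASIC_SEVA_35a.10
12 unique clips for 30 assemblies
30 48.01
```

30 designs are produced, one per marker × ori combination. Only 12 clip
reactions are needed: the cassette clip is shared by all 30 assemblies
(`total_assemblies = 30`), and each of the 6 marker and 5 ori clips is
shared along its row or column of the grid. The 48.01 ng is the mass of
the 1036 bp cassette part that yields 2.5 nM in a 30 µl clip reaction.

The same pipeline is scriptable from the shell:

```sh
basicdna demo-seva -o seva_demo --seed 1   # 30 GenBank files, build.json,
                                           # Echo picklists, manual protocol
basicdna validate-build seva_demo/build.json
basicdna list-collections
```

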